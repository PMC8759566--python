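"""miRNA-driven gene-set enrichment by logistic regression.

Each miRNA gets a signed significance score S_miRNA = -log10(FDR) * sign(LFC)
from a background-corrected metastasis-vs-primary DE table; each gene's
S_mRNA is the sum of S_miRNA over all miRNAs predicted to target it (genes
with no predicted regulator score 0, an informative zero).  A gene set is
then scored by logistic regression of set membership on S_mRNA over the gene
universe: a positive slope means members are preferentially targeted by
up-regulated miRNAs, i.e. the set is more suppressed; p-values are
BH-corrected within each collection.

The background correction interpolates toward the null in proportion to the
background effect: with a significant same-sign background of magnitude
|LFC_bg|, r = min(1, |LFC_bg| / |LFC|), LFC' = LFC * (1 - r) and
fdr' = fdr + r * (1 - fdr), which reduces LFC toward 0 and pushes FDR toward
1, reaching them exactly when the background matches or exceeds the
foreground.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

__all__ = [
    "GeneSetResult",
    "background_correct",
    "s_mirna",
    "s_mrna",
    "geneset_logistic",
    "run_gsea",
    "read_gmt",
    "write_gmt",
]

FDR_FLOOR = 1e-300  # keeps -log10 finite


@dataclass
class GeneSetResult:
    set_id: str
    b1: float
    se_b1: float
    p: float
    n_members: int
    direction: str  # "more_suppressed" iff b1 > 0
    separated: bool = False


# ---------------------------------------------------------------------------
# GMT I/O (one set per line: id <tab> description <tab> members...)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = fields[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for sid, members in sets.items():
            desc = (descriptions or {}).get(sid, "na")
            fh.write("\t".join([sid, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# scoring


def background_correct(
    de: pd.DataFrame,
    bg: pd.DataFrame | None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Attenuate foreground LFC/FDR by significant same-sign background.

    ``de`` needs columns lfc and fdr (index = miRNA); ``bg`` likewise, with
    the same sign orientation.  Without a background entry, with a
    non-significant background (fdr_bg >= 0.05) or with an opposite-sign
    background, a miRNA is unchanged.  An LFC of exactly 0 with significant
    same-sign background is left unchanged (r undefined, treated as 0).
    """
    out = de.copy()
    if bg is None:
        return out
    for m in out.index:
        if m not in bg.index:
            continue
        lfc, fdr = out.at[m, "lfc"], out.at[m, "fdr"]
        lfc_bg, fdr_bg = bg.at[m, "lfc"], bg.at[m, "fdr"]
        if (not np.isfinite(lfc_bg) or not np.isfinite(fdr_bg)
                or fdr_bg >= fdr_threshold or lfc == 0
                or np.sign(lfc_bg) != np.sign(lfc)):
            continue
        r = min(1.0, abs(lfc_bg) / abs(lfc))
        out.at[m, "lfc"] = lfc * (1.0 - r)
        out.at[m, "fdr"] = fdr + r * (1.0 - fdr)
    return out


def s_mirna(fdr: float, lfc: float) -> float:
    """Signed significance score: -log10(fdr) * sign(lfc); sign(0) = 0."""
    if not 0 <= fdr <= 1:
        raise ValueError(f"fdr {fdr} outside [0, 1]")
    return -np.log10(max(fdr, FDR_FLOOR)) * float(np.sign(lfc))


def s_mrna(scores: dict[str, float] | pd.Series,
           interactions: pd.DataFrame) -> pd.Series:
    """Per-gene sum of S_miRNA over its predicted regulators.

    ``interactions`` has columns mirna_id and gene_id; duplicate pairs count
    once; interaction miRNAs missing from ``scores`` are skipped with a
    warning.  Genes absent from the interaction map are absent here (they
    score 0 by contract and are filled in by the caller's universe).
    """
    scores = pd.Series(scores, dtype=float)
    pairs = interactions[["mirna_id", "gene_id"]].drop_duplicates()
    known = pairs["mirna_id"].isin(scores.index)
    if not known.all():
        import warnings
        missing = sorted(pairs.loc[~known, "mirna_id"].unique())
        warnings.warn(f"{len(missing)} interaction miRNA(s) without scores "
                      f"skipped: {missing[:5]}...")
        pairs = pairs[known]
    vals = scores.loc[pairs["mirna_id"]].to_numpy()
    return pd.Series(vals, index=pairs["gene_id"].to_numpy()).groupby(
        level=0).sum().rename("s_mrna")


# ---------------------------------------------------------------------------
# logistic regression


def _logistic_irls(x: np.ndarray, yb: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, bool]:
    """Two-parameter logistic MLE by IRLS.  Returns (beta, se, converged)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    p0 = np.clip(yb.mean(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(p0 / (1 - p0))
    converged = False

    def loglik(b: np.ndarray) -> float:
        eta = np.clip(X @ b, -30, 30)
        return float(yb @ eta - np.logaddexp(0.0, eta).sum())

    ll = loglik(beta)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        H = (X.T * w) @ X
        g = X.T @ (yb - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the likelihood monotone; under (quasi-)
        # separation the slope then diverges in the correct direction
        # instead of oscillating
        for _half in range(25):
            cand = beta + step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        else:
            break
        moved = np.max(np.abs(step))
        beta, ll = cand, ll_new
        if moved < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    return beta, se, converged


def geneset_logistic(
    scores: pd.Series,
    set_members: set[str] | list[str],
    universe: list[str] | None = None,
    min_overlap: int = 5,
) -> GeneSetResult:
    """Score one gene set: logit P(g in set) = b0 + b1 * S_mRNA(g).

    The fit runs over the gene universe (default: the score index); genes
    missing a score contribute 0.  Apparent perfect separation (no
    convergence or exploding SE) is flagged and yields p = NaN.
    """
    if universe is None:
        universe = list(scores.index)
    members = set(set_members) & set(universe)
    n_in = len(members)
    if n_in < min_overlap or len(universe) - n_in < min_overlap:
        raise ValueError(
            f"set overlap {n_in} of universe {len(universe)} outside "
            f"[{min_overlap}, |universe| - {min_overlap}]")
    x = scores.reindex(universe).fillna(0.0).to_numpy()
    yb = np.array([g in members for g in universe], dtype=float)
    beta, se, converged = _logistic_irls(x, yb)
    b1, se_b1 = float(beta[1]), float(se[1])
    separated = (not converged) or not np.isfinite(se_b1) or se_b1 > 1e3 \
        or abs(beta[1]) > 25
    if separated or se_b1 == 0:
        p = np.nan
    else:
        p = float(2.0 * stats.norm.sf(abs(b1 / se_b1)))
    set_id = getattr(set_members, "name", "geneset")
    return GeneSetResult(
        set_id=set_id if isinstance(set_id, str) else "geneset",
        b1=b1, se_b1=se_b1, p=p, n_members=n_in,
        direction="more_suppressed" if b1 > 0 else "less_suppressed",
        separated=separated,
    )


def run_gsea(
    de: pd.DataFrame,
    interactions: pd.DataFrame,
    collections: dict[str, dict[str, list[str]]],
    bg: pd.DataFrame | None = None,
    fdr_threshold: float = 0.05,
    min_overlap: int = 5,
) -> pd.DataFrame:
    """Full enrichment pass: background-correct, score miRNAs and genes,
    fit the logistic model per set and BH-adjust within each collection.

    ``de``/``bg``: DataFrames with columns lfc and fdr indexed by miRNA.
    ``collections``: {collection_name: {set_id: [genes]}}.  The gene universe
    is the union of interaction-map genes and collection members present in
    the score index contract: untargeted genes count as zeros.
    """
    corrected = background_correct(de, bg, fdr_threshold)
    mirna_scores = pd.Series(
        {m: s_mirna(row["fdr"], row["lfc"])
         for m, row in corrected.iterrows()
         if np.isfinite(row["fdr"]) and np.isfinite(row["lfc"])})
    gene_scores = s_mrna(mirna_scores, interactions)
    rows = []
    for coll_name, sets in collections.items():
        universe = sorted(set(gene_scores.index)
                          | {g for members in sets.values() for g in members})
        if not universe:
            raise ValueError(f"empty gene universe for collection {coll_name}")
        for sid, members in sets.items():
            try:
                res = geneset_logistic(gene_scores, members, universe,
                                       min_overlap)
            except ValueError:
                continue
            rows.append({"collection": coll_name, "set_id": sid,
                         "b1": res.b1, "se_b1": res.se_b1, "p": res.p,
                         "n_members": res.n_members,
                         "direction": res.direction,
                         "separated": res.separated})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = np.nan
        for coll_name in out["collection"].unique():
            idx = out["collection"] == coll_name
            out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p"].to_numpy())
        out = out.sort_values(["collection", "fdr", "set_id"]
                              ).reset_index(drop=True)
    return out
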