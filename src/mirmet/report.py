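"""Visualization-ready tables: UMAP embedding, volcano and CI tables.

UMAP is delegated to the umap-learn implementation (it is an interface here,
not a reimplementation); the embedding output records the parameters and
seed used so runs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["embed_umap", "volcano_table", "lfc_ci_table", "run_manifest"]


def embed_umap(
    vst: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D UMAP embedding of samples from a VST expression matrix.

    ``vst`` has miRNAs as rows and samples as columns.  Returns one row per
    sample with UMAP1/UMAP2 plus tissue/study annotation when metadata is
    given; parameters are recorded in ``attrs``.
    """
    import umap  # deferred: heavy import

    X = vst.T.to_numpy(dtype=float)
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need >= n_neighbors + 1 = {n_neighbors + 1} samples, "
            f"got {X.shape[0]}")
    reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                        n_components=2, random_state=seed)
    coords = reducer.fit_transform(X)
    out = pd.DataFrame(coords, index=vst.columns, columns=["UMAP1", "UMAP2"])
    if meta is not None:
        for col in ("tissue", "study"):
            if col in meta.columns:
                out[col] = meta.loc[out.index, col]
    out.attrs["params"] = {"n_neighbors": n_neighbors, "min_dist": min_dist,
                           "seed": seed}
    return out


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot table: per tested miRNA, LFC, -log10 FDR and the
    relevance flag; rows with NaN p-values are excluded."""
    ok = de["p_value"].notna()
    out = pd.DataFrame({
        "lfc": de.loc[ok, "LFC_shrunk"],
        "neg_log10_fdr": -np.log10(de.loc[ok, "fdr"].clip(lower=1e-300)),
        "relevant": de.loc[ok, "relevant"],
    })
    return out


def lfc_ci_table(de: pd.DataFrame, z: float = 1.96) -> pd.DataFrame:
    """95% normal-approximation confidence intervals: LFC +/- 1.96 * SE."""
    lfc = de["LFC_mle"]
    se = de["SE"]
    return pd.DataFrame({
        "lfc": lfc,
        "ci_low": lfc - z * se,
        "ci_high": lfc + z * se,
    })


def run_manifest(config: dict, seed: int | None,
                 input_paths: list[str | Path]) -> dict:
    """Reproducibility manifest: config hash, seed and input checksums."""
    checksums = {}
    for p in input_paths:
        p = Path(p)
        h = hashlib.sha256()
        h.update(p.read_bytes())
        checksums[str(p)] = h.hexdigest()
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    return {"config_sha256": cfg_hash, "seed": seed,
            "input_sha256": checksums}
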