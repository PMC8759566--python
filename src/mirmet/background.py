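"""Normal-tissue background correction of site-specific DE calls.

A miRNA that is abundant in the host organ of a metastasis (hepatocyte miRNAs
in liver, for instance) will look differentially expressed in bulk
metastasis-vs-primary comparisons purely because of tissue composition.  The
correction builds, per metastatic site, a signed set of miRNAs differentially
expressed between the site's normal tissue and colorectal tissue (nCR-vs-nSite
and pCRC-vs-nSite contrasts, union), and removes site calls whose direction
matches the background.  Peritoneal metastases have no adjacent normal, so the
union of the liver and lung background sets is used.

Sign convention (fixed throughout): positive = higher at the metastatic /
normal-site organ than in the colorectal reference, for both foreground and
background contrasts, so "same direction" is an equality of signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BackgroundSet",
    "build_background_set",
    "apply_background_filter",
    "union_background",
    "multi_site_summary",
]

BG_MODES = ("union", "ncr_only", "pcrc_only", "intersection")


@dataclass
class BackgroundSet:
    site: str
    #: miRNA -> set of signs (+1/-1); both signs possible when the two
    #: contributing contrasts disagree
    entries: dict[str, set[int]] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def add(self, mirna: str, sign: int) -> None:
        self.entries.setdefault(mirna, set()).add(int(np.sign(sign)))

    def suppresses(self, mirna: str, sign: int) -> bool:
        return int(np.sign(sign)) in self.entries.get(mirna, set())


def _signed_relevant(de: pd.DataFrame) -> dict[str, int]:
    rel = de[de["relevant"]]
    return {m: (1 if lfc > 0 else -1)
            for m, lfc in rel["LFC_shrunk"].items() if lfc != 0}


def build_background_set(
    de_ncr_vs_nsite: pd.DataFrame | None,
    de_pcrc_vs_nsite: pd.DataFrame | None,
    site: str,
    mode: str = "union",
) -> BackgroundSet:
    """Signed background set for one site from the two normal-tissue contrasts.

    Both inputs must be oriented as site-normal minus colorectal reference
    (positive = higher in nSite); a miRNA enters the set, with its sign, when
    it passes the relevance filter in either contrast (mode ``union``, the
    default) or per the chosen combination mode.
    """
    if mode not in BG_MODES:
        raise ValueError(f"mode must be one of {BG_MODES}")
    contrasts = {"nCR_vs_nSite": de_ncr_vs_nsite,
                 "pCRC_vs_nSite": de_pcrc_vs_nsite}
    if mode == "ncr_only":
        contrasts.pop("pCRC_vs_nSite")
    elif mode == "pcrc_only":
        contrasts.pop("nCR_vs_nSite")
    signed = {}
    for name, de in contrasts.items():
        if de is None:
            raise ValueError(f"contrast {name} required for mode {mode!r}")
        if "relevant" not in de.columns:
            raise ValueError(
                f"contrast {name} lacks relevance flags; run the DE pipeline "
                "with the relevance filter (orientation must be explicit)")
        signed[name] = _signed_relevant(de)
    bg = BackgroundSet(site=site, provenance=sorted(signed))
    if mode == "intersection":
        (n1, s1), (n2, s2) = signed.items()
        for m in set(s1) & set(s2):
            if s1[m] == s2[m]:
                bg.add(m, s1[m])
    else:
        for s in signed.values():
            for m, sign in s.items():
                bg.add(m, sign)
    return bg


def apply_background_filter(calls: pd.DataFrame,
                            bg: BackgroundSet,
                            site: str | None = None) -> pd.DataFrame:
    """Suppress relevant site-vs-primary calls whose sign matches the
    background; opposite-sign background never suppresses.

    ``calls`` is a DE table (metastasis minus pCRC orientation) with
    LFC_shrunk and relevance flags.  Returns the table with
    relevant_before_bg, suppressed_by_background and final_call columns.
    """
    if site is not None and site != bg.site:
        raise ValueError(f"site mismatch: calls for {site}, background for "
                         f"{bg.site}")
    out = calls.copy()
    lfc = out["LFC_shrunk"]
    out["relevant_before_bg"] = out["relevant"]
    out["suppressed_by_background"] = [
        bg.suppresses(m, lfc.loc[m]) if lfc.loc[m] != 0 else False
        for m in out.index
    ]
    out["final_call"] = out["relevant_before_bg"] & ~out["suppressed_by_background"]
    return out


def union_background(bg_liver: BackgroundSet,
                     bg_lung: BackgroundSet,
                     site: str = "PM") -> BackgroundSet:
    """Signed union of the liver and lung background sets (for PM, which has
    no adjacent normal tissue)."""
    bg = BackgroundSet(site=site,
                       provenance=sorted(set(bg_liver.provenance)
                                         | set(bg_lung.provenance)))
    for src in (bg_liver, bg_lung):
        for m, signs in src.entries.items():
            for s in signs:
                bg.add(m, s)
    return bg


def multi_site_summary(calls_per_site: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Tabulate miRNAs by the number of sites with a final call.

    One row per miRNA with >= 1 final call: the sites, per-site signs, the
    count and a mixed-direction flag; sorted by count descending then id.
    """
    rows = {}
    for site, calls in calls_per_site.items():
        final = calls[calls["final_call"]]
        for m, lfc in final["LFC_shrunk"].items():
            entry = rows.setdefault(m, {"sites": [], "signs": []})
            entry["sites"].append(site)
            entry["signs"].append(1 if lfc > 0 else -1)
    records = [
        {
            "mirna": m,
            "n_sites": len(e["sites"]),
            "sites": ",".join(e["sites"]),
            "signs": ",".join("+" if s > 0 else "-" for s in e["signs"]),
            "mixed_direction": len(set(e["signs"])) > 1,
        }
        for m, e in rows.items()
    ]
    df = pd.DataFrame(records,
                      columns=["mirna", "n_sites", "sites", "signs",
                               "mixed_direction"])
    if len(df):
        df = df.sort_values(["n_sites", "mirna"],
                            ascending=[False, True]).reset_index(drop=True)
    return df
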