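"""Coverage-based sex-chromosome scaffold assignment.

In a ZW system the female (ZW) carries one Z where the male (ZZ) carries
two, so Z-specific scaffolds sequence at half depth in females and sit
near log2(female:male) = -1 while autosomes sit near 0.  Scaffolds are
classified by where their log2 ratio falls relative to the genome-wide
median, using zones anchored on that median so the classification is
invariant to global depth differences between the two libraries.

The same machinery run with reversed polarity (looking for "pseudo-X"
scaffolds at +1, which cannot exist in a true ZW system) provides an
empirical false-positive yardstick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ZoneSpec",
    "ZONE_PRESETS",
    "coverage_filter",
    "log2_ratio_table",
    "assign_scaffolds",
    "pseudo_x_assignment",
    "assign_coverage",
    "map_transcripts",
    "locate_genes",
]


@dataclass(frozen=True)
class ZoneSpec:
    """Zone boundaries, as offsets from the median log2(F:M) ratio.

    The Z zone is closed on both ends; the autosome zone is open (its lower
    bound coincides with the Z upper bound, so exact-boundary scaffolds go
    deterministically to Z).  The X zone is used only under XY polarity.
    """

    z_low: float = -2.0
    z_high: float = -0.5
    a_low: float = -0.5
    a_high: float = 2.0
    x_low: float = 0.5
    x_high: float = 2.0

    def __post_init__(self) -> None:
        if not (self.z_low < self.z_high <= self.a_low < self.a_high):
            raise ValueError("require z_low < z_high <= a_low < a_high")


#: the default zones plus the three stricter robustness variants
ZONE_PRESETS: dict[str, ZoneSpec] = {
    "default": ZoneSpec(),
    "t1": ZoneSpec(z_high=-0.6, a_low=-0.4),
    "t2": ZoneSpec(z_high=-0.7, a_low=-0.3),
    "t3": ZoneSpec(z_high=-0.8, a_low=-0.2),
}

_COV_COLS = ["scaffold_id", "length", "mean_depth_female", "mean_depth_male"]


def _check_coverage(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(_COV_COLS) - set(records.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    if (records["length"] <= 0).any():
        raise ValueError("scaffold lengths must be > 0")
    if (records[["mean_depth_female", "mean_depth_male"]] < 0).to_numpy().any():
        raise ValueError("depths must be >= 0")
    return records


def _depth_center(records: pd.DataFrame, column: str, center: str) -> float:
    """Genome-wide depth summary for one sex.

    ``mean`` is the length-weighted mean depth (total bases / total length);
    ``median`` is the unweighted median of per-scaffold depths.
    """
    if center == "mean":
        return float(np.average(records[column], weights=records["length"]))
    if center == "median":
        return float(records[column].median())
    raise ValueError("center must be 'mean' or 'median'")


def coverage_filter(records: pd.DataFrame, min_len: int = 5000,
                    polarity: str = "ZW", center: str = "mean") -> pd.DataFrame:
    """Drop short scaffolds and coverage outliers before ratio analysis.

    Retains scaffolds with length strictly greater than ``min_len``, depth
    in the reference sex at least 1/4 of that sex's genome-wide average,
    and depth in each sex at most 4x that sex's average.  The reference
    sex is the homogametic one: male for ZW polarity, female for the
    reverse (pseudo-X) control.  The 1/4 floor in the homogametic sex
    keeps hemizygous scaffolds (at ~1/2 dose in the other sex) while
    removing unsequenced or repetitive junk; the 4x ceiling removes
    collapsed repeats.
    """
    _check_coverage(records)
    if len(records) == 0:
        raise ValueError("no coverage records supplied")
    if polarity not in ("ZW", "XY"):
        raise ValueError("polarity must be 'ZW' or 'XY'")
    avg_f = _depth_center(records, "mean_depth_female", center)
    avg_m = _depth_center(records, "mean_depth_male", center)
    ref_col, ref_avg = (("mean_depth_male", avg_m) if polarity == "ZW"
                        else ("mean_depth_female", avg_f))
    keep = (
        (records["length"] > min_len)
        & (records[ref_col] >= ref_avg / 4.0)
        & (records["mean_depth_female"] <= 4.0 * avg_f)
        & (records["mean_depth_male"] <= 4.0 * avg_m)
    )
    retained = records.loc[keep]
    if len(retained) == 0:
        raise ValueError("no scaffolds survive filters")
    return retained


def log2_ratio_table(retained: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """log2(female:male) depth ratio per scaffold, centered on the median.

    The median is computed unweighted over the retained scaffolds.  The
    coverage filters guarantee both depths are positive for every retained
    scaffold, so no pseudocounts are used.
    """
    if len(retained) == 0:
        raise ValueError("empty ratio input")
    if (retained[["mean_depth_female", "mean_depth_male"]] <= 0).to_numpy().any():
        raise ValueError("retained scaffolds must have positive depth in both sexes")
    log2_fm = np.log2(retained["mean_depth_female"] / retained["mean_depth_male"])
    median = float(np.median(log2_fm))
    out = pd.DataFrame(
        {
            "scaffold_id": retained["scaffold_id"].to_numpy(),
            "log2_fm": log2_fm.to_numpy(),
            "centered": log2_fm.to_numpy() - median,
        }
    )
    return out, median


def assign_scaffolds(ratios: pd.DataFrame, zones: ZoneSpec = ZoneSpec()) -> pd.DataFrame:
    """Classify each retained scaffold as Z, autosome or unassigned."""
    c = ratios["centered"].to_numpy()
    cls = np.full(len(ratios), "unassigned", dtype=object)
    cls[(c > zones.a_low) & (c < zones.a_high)] = "autosome"
    cls[(c >= zones.z_low) & (c <= zones.z_high)] = "Z"
    out = ratios.copy()
    out["class"] = cls
    return out


def pseudo_x_assignment(ratios: pd.DataFrame, zones: ZoneSpec = ZoneSpec()) -> pd.DataFrame:
    """Scaffolds in the pseudo-X zone (reverse-polarity false-positive control)."""
    c = ratios["centered"]
    return ratios.loc[(c >= zones.x_low) & (c <= zones.x_high)].copy()


def assign_coverage(records: pd.DataFrame, min_len: int = 5000,
                    zones: ZoneSpec = ZoneSpec(), polarity: str = "ZW",
                    center: str = "mean") -> tuple[pd.DataFrame, float]:
    """Full assignment: filter, ratio, zones; every input scaffold classed.

    Returns (table, median) where the table has one row per *input*
    scaffold with columns scaffold_id, log2_fm, centered, class; scaffolds
    removed by the coverage filters get class "filtered" (NaN ratios).
    Under XY polarity the positive zone yields class "pseudo-X" instead
    of "Z".
    """
    retained = coverage_filter(records, min_len=min_len, polarity=polarity, center=center)
    ratios, median = log2_ratio_table(retained)
    if polarity == "ZW":
        assigned = assign_scaffolds(ratios, zones)
    else:
        c = ratios["centered"].to_numpy()
        cls = np.full(len(ratios), "unassigned", dtype=object)
        # autosome zone mirrored: between -a_high and +x_low (open at x_low)
        cls[(c > -zones.a_high) & (c < zones.x_low)] = "autosome"
        cls[(c >= zones.x_low) & (c <= zones.x_high)] = "pseudo-X"
        assigned = ratios.copy()
        assigned["class"] = cls
    out = records[["scaffold_id"]].merge(assigned, on="scaffold_id", how="left")
    out["class"] = out["class"].fillna("filtered")
    return out, median


def map_transcripts(assignments: pd.DataFrame,
                    transcript_map: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Propagate scaffold classes to transcripts; count per class.

    ``transcript_map`` needs columns (transcript, scaffold_id).  Transcripts
    on scaffolds absent from the assignment table get class "unplaced".
    """
    if transcript_map["transcript"].duplicated().any():
        dup = transcript_map.loc[transcript_map["transcript"].duplicated(), "transcript"]
        raise ValueError(f"duplicate transcript ids: {sorted(set(dup))[:5]}")
    cls = assignments.set_index("scaffold_id")["class"]
    out = transcript_map.copy()
    out["class"] = out["scaffold_id"].map(cls).fillna("unplaced")
    return out, out["class"].value_counts()


def locate_genes(assignments: pd.DataFrame, gene_map: pd.DataFrame) -> pd.DataFrame:
    """Report the scaffold, log2(F:M) ratio and class for candidate genes.

    ``gene_map`` needs columns (gene, scaffold_id).  Genes whose scaffold
    is not in the assignment table are reported as "no assignment".
    """
    idx = assignments.set_index("scaffold_id")
    rows = []
    for gene, scaf in gene_map[["gene", "scaffold_id"]].itertuples(index=False):
        if scaf in idx.index:
            rows.append((gene, scaf, idx.at[scaf, "log2_fm"], idx.at[scaf, "class"]))
        else:
            rows.append((gene, scaf, np.nan, "no assignment"))
    return pd.DataFrame(rows, columns=["gene", "scaffold_id", "log2_fm", "class"])
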