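"""qPCR copy-number validation of Z-linkage via the delta-delta-Cq method.

On a Z-specific locus, ZZ males carry two template copies where ZW
females carry one, so with 100% amplification efficiency the male
reaction crosses threshold one cycle earlier and the male:female relative
quantity is 2^1 = 2.  Target Cq values are normalized to autosomal
reference genes within each individual (delta-Cq), calibrated against the
female group mean (delta-delta-Cq), and converted to fold = 2^(-ddCq).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["relative_quantity", "z_linkage_call", "analyze_qpcr"]

#: male:female fold windows for the linkage call; a Z locus is expected at
#: 2.0, an autosomal one at 1.0, with a deliberate indeterminate gap between
Z_WINDOW = (1.5, 3.0)
AUTOSOMAL_WINDOW = (0.67, 1.33)


def relative_quantity(cq_target: float, cq_reference: float,
                      calibrator_delta: float) -> float:
    """Fold quantity 2^(-ddCq) for one measurement.

    dCq = cq_target - cq_reference (reference = mean over reference
    genes); ddCq = dCq - calibrator_delta.  Assumes 100% amplification
    efficiency (quantity doubles per cycle).
    """
    for v in (cq_target, cq_reference, calibrator_delta):
        if not np.isfinite(v):
            raise ValueError("Cq inputs must be finite")
    return float(2.0 ** -((cq_target - cq_reference) - calibrator_delta))


def z_linkage_call(fold_male_over_female: float) -> str:
    """Classify a locus from its male:female relative copy number."""
    if fold_male_over_female <= 0:
        raise ValueError("fold must be > 0")
    lo, hi = Z_WINDOW
    if lo <= fold_male_over_female <= hi:
        return "Z_linked"
    lo, hi = AUTOSOMAL_WINDOW
    if lo <= fold_male_over_female <= hi:
        return "autosomal"
    return "indeterminate"


def analyze_qpcr(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene male:female fold and Z-linkage call from a Cq table.

    ``cq_table`` columns: individual, sex, gene, cq, role (target |
    reference).  Technical replicates are averaged.  Per individual,
    dCq(gene) = mean Cq(gene) - mean Cq(reference genes); the calibrator
    for each target gene is the mean dCq of the female group, making the
    female mean fold 1 by construction.  The male:female ratio is the
    geometric mean fold of the male group (equivalently
    2^-(mean male dCq - mean female dCq)).
    """
    required = {"individual", "sex", "gene", "cq", "role"}
    if not required.issubset(cq_table.columns):
        raise ValueError(f"Cq table needs columns {sorted(required)}")
    if (cq_table["cq"] <= 0).any():
        raise ValueError("Cq values must be > 0")
    ref = cq_table.loc[cq_table["role"] == "reference"]
    ref_by_ind = ref.groupby("individual")["cq"].mean()
    targets = cq_table.loc[cq_table["role"] == "target"]
    missing_ref = set(targets["individual"]) - set(ref_by_ind.index)
    if missing_ref:
        raise ValueError(f"no reference measurement for: {sorted(missing_ref)}")

    rows = []
    for gene, sub in targets.groupby("gene"):
        per_ind = sub.groupby(["individual", "sex"])["cq"].mean().reset_index()
        per_ind["dcq"] = per_ind["cq"] - per_ind["individual"].map(ref_by_ind).astype(float)
        means = per_ind.groupby("sex")["dcq"].mean()
        if not {"female", "male"}.issubset(means.index):
            raise ValueError(f"gene {gene!r} needs measurements in both sexes")
        calibrator = means["female"]
        fold_m = float(2.0 ** -(means["male"] - calibrator))
        rows.append((gene, means["female"], means["male"], fold_m,
                     z_linkage_call(fold_m)))
    return pd.DataFrame(
        rows, columns=["gene", "mean_dcq_female", "mean_dcq_male",
                       "fold_male_over_female", "call"]
    ).sort_values("gene", ignore_index=True)
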