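"""Detection of young, coverage-undifferentiated ZW strata from pooled SNPs.

A region of the Z that stopped recombining with the W only recently still
co-assembles with its W homolog, so it shows no coverage dip in females.
It is detectable instead through fixed Z/W differences: sites heterozygous
in every female pool (ZW) and homozygous in every male pool (ZZ).
Scaffolds already classed as autosomal by coverage but enriched for such
ZW-consistent SNPs are flagged as the putative young stratum; the calls
are cross-validated in the two DNA individuals and benchmarked against
the reverse (XY-consistent) pattern, which can only arise from noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import HET, HOM_ALT, HOM_REF, MISSING, NO_CALL

__all__ = [
    "VariantTable",
    "read_vcf",
    "filter_sites",
    "call_genotype",
    "call_genotypes",
    "classify_site",
    "classify_sites",
    "summarize_scaffolds",
    "cross_validate_dna",
    "EnrichmentResult",
    "proportion_chisq",
    "run_polarity",
    "reverse_control",
]

STATE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt",
               NO_CALL: "no_call", MISSING: "missing"}


@dataclass
class VariantTable:
    """Biallelic SNP sites with per-sample allele depths.

    ``meta`` has one row per site (scaffold_id, pos, ref, alt, qual);
    ``ref_depth``/``alt_depth`` are (n_sites, n_samples) integer arrays in
    the order of ``samples``; ``sheet`` maps sample -> (sex, material).
    """

    meta: pd.DataFrame
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    samples: list[str]
    sheet: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValueError("negative read depth")
        if self.ref_depth.shape != (len(self.meta), len(self.samples)):
            raise ValueError("depth array shape mismatch")

    def sample_indices(self, sex: str, material: str) -> list[int]:
        names = self.sheet.loc[
            (self.sheet["sex"] == sex) & (self.sheet["material"] == material), "sample"
        ]
        return [self.samples.index(s) for s in names]


def read_vcf(vcf_path, sample_sheet: pd.DataFrame) -> VariantTable:
    """Load a VCF with per-sample AD into a :class:`VariantTable`.

    Non-SNP and multi-allelic records are dropped here (the upstream
    caller keeps a maximum of two alleles and no indels); all remaining
    filtering is done by :func:`filter_sites`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing = set(sample_sheet["sample"]) - set(samples)
    if missing:
        raise ValueError(f"sample sheet names absent from VCF: {sorted(missing)}")
    meta_rows, refs, alts = [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # indel or multi-allelic
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"site {v.CHROM}:{v.POS} lacks AD")
        ad = np.maximum(ad, 0)  # cyvcf2 encodes missing as negative
        meta_rows.append((v.CHROM, v.POS, v.REF, v.ALT[0],
                          float(v.QUAL) if v.QUAL is not None else 0.0))
        refs.append(ad[:, 0])
        alts.append(ad[:, 1])
    meta = pd.DataFrame(meta_rows, columns=["scaffold_id", "pos", "ref", "alt", "qual"])
    shape = (len(meta), len(samples))
    return VariantTable(
        meta,
        np.array(refs, dtype=np.int64).reshape(shape),
        np.array(alts, dtype=np.int64).reshape(shape),
        samples,
        sample_sheet,
    )


def from_dataframe(variants: pd.DataFrame, sheet: pd.DataFrame) -> VariantTable:
    """Build a :class:`VariantTable` from the simulator's wide DataFrame."""
    samples = list(sheet["sample"])
    meta_cols = [c for c in ("scaffold_id", "pos", "ref", "alt", "qual", "true_zw")
                 if c in variants.columns]
    return VariantTable(
        variants[meta_cols].reset_index(drop=True),
        variants[[f"{s}.ref" for s in samples]].to_numpy(dtype=np.int64),
        variants[[f"{s}.alt" for s in samples]].to_numpy(dtype=np.int64),
        samples,
        sheet,
    )


def filter_sites(table: VariantTable, min_depth: int = 10,
                 min_qual: float = 20.0) -> VariantTable:
    """Apply the site-quality and depth filters.

    Sites with QUAL <= ``min_qual`` (strict ``>`` rule) are dropped
    entirely; per-sample observations with total depth < ``min_depth``
    are masked as missing (depths zeroed) rather than dropping the site.
    """
    keep = table.meta["qual"].to_numpy() > min_qual
    meta = table.meta.loc[keep].reset_index(drop=True)
    ref = table.ref_depth[keep].copy()
    alt = table.alt_depth[keep].copy()
    shallow = (ref + alt) < min_depth
    ref[shallow] = 0
    alt[shallow] = 0
    return VariantTable(meta, ref, alt, table.samples, table.sheet)


def call_genotype(ref_depth: int, alt_depth: int) -> int:
    """Genotype one observation from its ref/alt read depths.

    Alt fraction a: a >= 0.85 -> hom_alt, a <= 0.15 -> hom_ref; het only
    if the minor allele strictly exceeds 30% of reads; the ambiguous band
    (0.15, 0.30] is a no-call, applying the pooled-sample heterozygote
    guard on top of the homozygote floor without inventing a genotype.
    """
    total = ref_depth + alt_depth
    if total == 0:
        raise ValueError("zero total depth")
    # integer comparisons keep the boundaries exact: a minor count of
    # exactly 30% of reads has not "exceeded 30%"
    if 20 * alt_depth >= 17 * total:
        return HOM_ALT
    if 20 * alt_depth <= 3 * total:
        return HOM_REF
    if 10 * min(ref_depth, alt_depth) > 3 * total:
        return HET
    return NO_CALL


def call_genotypes(table: VariantTable, min_depth: int = 10) -> np.ndarray:
    """Vectorized genotype calls, (n_sites, n_samples) state-code array.

    Observations with total depth < ``min_depth`` are MISSING.
    """
    ref, alt = table.ref_depth, table.alt_depth
    total = ref + alt
    calls = np.full(total.shape, NO_CALL, dtype=np.int8)
    calls[20 * alt >= 17 * total] = HOM_ALT
    calls[20 * alt <= 3 * total] = HOM_REF
    calls[10 * np.minimum(ref, alt) > 3 * total] = HET
    calls[total < min_depth] = MISSING
    return calls


def classify_site(female_calls, male_calls, polarity: str = "ZW") -> str:
    """Classify one site from its 4 female and 4 male pool genotypes.

    ZW polarity: heterozygous in *all* female pools and homozygous in
    *all* male pools -> "consistent".  XY mirrors with the sexes swapped.
    Any no-call or missing among the eight pools -> "unassessable".
    """
    female_calls, male_calls = list(female_calls), list(male_calls)
    if len(female_calls) != 4 or len(male_calls) != 4:
        raise ValueError("expected 4 pools per sex")
    if polarity not in ("ZW", "XY"):
        raise ValueError("polarity must be 'ZW' or 'XY'")
    eight = female_calls + male_calls
    if any(c in (NO_CALL, MISSING) for c in eight):
        return "unassessable"
    het_sex, hom_sex = (female_calls, male_calls) if polarity == "ZW" else (male_calls, female_calls)
    if all(c == HET for c in het_sex) and all(c in (HOM_REF, HOM_ALT) for c in hom_sex):
        return "consistent"
    return "other"


def classify_sites(table: VariantTable, polarity: str = "ZW",
                   min_depth: int = 10) -> pd.DataFrame:
    """Site classification for every site, vectorized over the RNA pools.

    Returns the site meta plus a ``site_class`` column in
    {consistent, other, unassessable}.
    """
    calls = call_genotypes(table, min_depth=min_depth)
    f_idx = table.sample_indices("female", "RNA_pool")
    m_idx = table.sample_indices("male", "RNA_pool")
    if len(f_idx) != 4 or len(m_idx) != 4:
        raise ValueError("expected 4 RNA pools per sex")
    f, m = calls[:, f_idx], calls[:, m_idx]
    assessable = ((f >= 0).all(axis=1)) & ((m >= 0).all(axis=1))
    het_sex, hom_sex = (f, m) if polarity == "ZW" else (m, f)
    consistent = ((het_sex == HET).all(axis=1)
                  & np.isin(hom_sex, (HOM_REF, HOM_ALT)).all(axis=1))
    out = table.meta.copy()
    out["site_class"] = np.where(~assessable, "unassessable",
                                 np.where(consistent, "consistent", "other"))
    return out


def summarize_scaffolds(site_classes: pd.DataFrame, assignments: pd.DataFrame,
                        min_snps: int = 10, min_prop: float = 0.20) -> pd.DataFrame:
    """Flag putative young-stratum scaffolds among the coverage-autosomes.

    Only scaffolds classed "autosome" by the coverage pipeline are
    scanned (a differentiated Z is already found by coverage; filtered
    scaffolds have unreliable depth).  Per scaffold, ``n_snps`` counts
    assessable sites and ``young_flag`` requires at least ``min_snps``
    of them with at least ``min_prop`` consistent.
    """
    auto = set(assignments.loc[assignments["class"] == "autosome", "scaffold_id"])
    sites = site_classes.loc[
        site_classes["scaffold_id"].isin(auto)
        & (site_classes["site_class"] != "unassessable")
    ]
    grp = sites.groupby("scaffold_id", sort=True)
    summary = pd.DataFrame(
        {
            "n_snps": grp.size(),
            "n_consistent": grp["site_class"].apply(lambda s: int((s == "consistent").sum())),
        }
    ).reset_index()
    summary["prop_consistent"] = summary["n_consistent"] / summary["n_snps"]
    summary["young_flag"] = (summary["n_snps"] >= min_snps) & (
        summary["prop_consistent"] >= min_prop
    )
    return summary


def cross_validate_dna(table: VariantTable, site_mask: np.ndarray,
                       polarity: str = "ZW", min_depth: int = 10
                       ) -> tuple[int, int, float]:
    """Check RNA-derived consistent sites against the two DNA individuals.

    ``site_mask`` selects the sites to validate (boolean over the table's
    sites).  A site is assessable when both DNA samples yield a genotype
    call at depth >= ``min_depth``; it validates when the heterogametic
    individual is het and the homogametic one homozygous.  Returns
    (n_assessable, n_consistent, proportion) with proportion NaN when
    nothing is assessable.
    """
    calls = call_genotypes(table, min_depth=min_depth)
    f_idx = table.sample_indices("female", "DNA_individual")
    m_idx = table.sample_indices("male", "DNA_individual")
    if len(f_idx) != 1 or len(m_idx) != 1:
        raise ValueError("expected one DNA individual per sex")
    f, m = calls[:, f_idx[0]], calls[:, m_idx[0]]
    assessable = site_mask & (f >= 0) & (m >= 0)
    het, hom = (f, m) if polarity == "ZW" else (m, f)
    consistent = assessable & (het == HET) & np.isin(hom, (HOM_REF, HOM_ALT))
    n_a, n_c = int(assessable.sum()), int(consistent.sum())
    return n_a, n_c, (n_c / n_a if n_a else float("nan"))


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 proportion comparison: k1/n1 vs k2/n2."""

    k1: int
    n1: int
    k2: int
    n2: int
    chi2: float
    p_value: float
    df: int = 1

    @property
    def fold(self) -> float:
        return (self.k1 / self.n1) / (self.k2 / self.n2) if self.k2 else float("nan")


def proportion_chisq(k1: int, n1: int, k2: int, n2: int) -> EnrichmentResult:
    """Yates-corrected Pearson chi-square comparing two proportions.

    Tests k1/n1 against k2/n2 on the 2x2 table [[k1, n1-k1], [k2, n2-k2]]
    with the continuity correction max(0, |O-E| - 0.5) applied to every
    cell (the R ``prop.test`` convention), df = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be > 0")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("require 0 <= k <= n")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    row, col = obs.sum(axis=1), obs.sum(axis=0)
    if (col == 0).any():
        return EnrichmentResult(k1, n1, k2, n2, 0.0, 1.0)
    expected = np.outer(row, col) / obs.sum()
    dev = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    return EnrichmentResult(k1, n1, k2, n2, chi2, float(stats.chi2.sf(chi2, df=1)))


def run_polarity(table: VariantTable, assignments: pd.DataFrame, polarity: str = "ZW",
                 min_depth: int = 10, min_qual: float = 20.0,
                 min_snps: int = 10, min_prop: float = 0.20) -> dict:
    """One full consistency analysis at a given polarity.

    Filters sites, classifies them, flags young-stratum scaffolds among
    the coverage-autosomes, and cross-validates in DNA both the
    young-stratum consistent SNPs and (as the genome-wide baseline) all
    consistent SNPs, returning the enrichment chi-square between the two
    validation rates.
    """
    filtered = filter_sites(table, min_depth=min_depth, min_qual=min_qual)
    site_classes = classify_sites(filtered, polarity=polarity, min_depth=min_depth)
    summary = summarize_scaffolds(site_classes, assignments,
                                  min_snps=min_snps, min_prop=min_prop)
    young = set(summary.loc[summary["young_flag"], "scaffold_id"])

    consistent = (site_classes["site_class"] == "consistent").to_numpy()
    on_young = site_classes["scaffold_id"].isin(young).to_numpy()
    young_consistent = consistent & on_young

    # DNA validation of the young-stratum candidate SNPs...
    n_a, n_c, prop = cross_validate_dna(filtered, young_consistent,
                                        polarity=polarity, min_depth=min_depth)
    # ...against the genome-wide baseline: all assessable RNA SNPs
    assessed = site_classes["site_class"].to_numpy() != "unassessable"
    base_a, base_c, base_prop = cross_validate_dna(filtered, assessed,
                                                   polarity=polarity, min_depth=min_depth)
    enrichment = (proportion_chisq(n_c, n_a, base_c, base_a)
                  if n_a and base_a else None)
    return {
        "polarity": polarity,
        "n_sites": int(len(site_classes)),
        "n_consistent": int(consistent.sum()),
        "n_young_scaffolds": int(len(young)),
        "young_scaffolds": sorted(young),
        "n_consistent_on_young": int(young_consistent.sum()),
        "dna_assessable": n_a,
        "dna_consistent": n_c,
        "dna_proportion": prop,
        "dna_baseline_assessable": base_a,
        "dna_baseline_consistent": base_c,
        "dna_baseline_proportion": base_prop,
        "dna_enrichment": enrichment,
        "site_classes": site_classes,
        "scaffold_summary": summary,
    }


def reverse_control(table: VariantTable, assignments: pd.DataFrame, **kwargs) -> dict:
    """Run both polarities and compare their stratum concentration.

    The XY run is the false-positive yardstick: in a true ZW system,
    XY-consistent SNPs can only arise from noise.  The returned
    ``concentration_chisq`` compares, between polarities, the fraction of
    consistent SNPs that fall on flagged (>= min_prop consistent)
    scaffolds.
    """
    zw = run_polarity(table, assignments, polarity="ZW", **kwargs)
    xy = run_polarity(table, assignments, polarity="XY", **kwargs)
    conc = None
    if zw["n_consistent"] and xy["n_consistent"]:
        conc = proportion_chisq(zw["n_consistent_on_young"], zw["n_consistent"],
                                xy["n_consistent_on_young"], xy["n_consistent"])
    return {"ZW": zw, "XY": xy, "concentration_chisq": conc}
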