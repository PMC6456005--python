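"""Synthetic ZW-system data generator.

Emulates the data structure of a female-heterogametic (ZW) sex-chromosome
study in a non-model crustacean: per-sex genomic depth of coverage over
assembly scaffolds, pooled RNA-seq genotypes for 4 female and 4 male pools
plus two inbred DNA individuals, an RNA-seq count matrix over a
2 tissues x 2 sexes x 2 replicates design, and qPCR Cq tables — all with
known ground truth so the discovery pipeline can be validated end to end.

Three scaffold classes are simulated:

* ``A``      — autosomal: equal depth in both sexes, sex-independent SNPs.
* ``Z``      — Z-specific (the W homolog is lost): half depth in females.
* ``youngZ`` — a young, coverage-undifferentiated ZW stratum: equal depth,
  but carrying fixed Z/W differences that appear heterozygous in every
  female pool and homozygous in every male pool.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimGenome",
    "expected_inbreeding",
    "simulate_genome",
    "simulate_coverage",
    "simulate_variants",
    "simulate_counts",
    "simulate_qpcr",
    "write_vcf",
    "simulate_all",
]

#: genotype state codes shared with :mod:`zwstrata.strata`
HOM_REF, HET, HOM_ALT, NO_CALL, MISSING = 0, 1, 2, -1, -2


@dataclass
class SimConfig:
    """All tunable parameters of the synthetic study.

    Defaults reproduce the study conditions the pipeline is validated
    against: a 500-scaffold genome sequenced at ~28x (female) and ~30x
    (male), four 5-individual pools per sex, and two DNA individuals from
    a line inbred by six generations of full-sib mating.
    """

    n_autosomal_scaffolds: int = 430
    n_z_scaffolds: int = 50
    n_youngz_scaffolds: int = 20
    scaffold_length_range: tuple[int, int] = (6_000, 60_000)
    depth_female: float = 28.0
    depth_male: float = 30.0
    depth_dispersion: float = 0.2  # CV of per-scaffold multiplicative noise
    snps_per_kb: float = 3.0
    pool_count_per_sex: int = 4
    pool_size: int = 5  # individuals per pool
    genotyping_error: float = 0.01  # P(called genotype is flipped)
    dna_missing_rate: float = 0.3  # P(a DNA individual lacks coverage at a site)
    zw_fixed_fraction: float = 0.5  # fraction of youngZ SNPs that are fixed Z/W differences
    n_transcripts: int = 2_000
    transcript_length_range: tuple[int, int] = (500, 3_000)
    compensation_scenario: str = "full"  # {"full", "none"}
    sexbias_fraction: float = 0.0
    sexbias_fold: float = 8.0
    count_dispersion: float = 0.05  # gamma-Poisson overdispersion
    inbreeding_generations: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_autosomal_scaffolds", "n_z_scaffolds", "n_youngz_scaffolds",
                     "pool_count_per_sex", "pool_size", "n_transcripts",
                     "inbreeding_generations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth_female <= 0 or self.depth_male <= 0:
            raise ValueError("depths must be > 0")
        for name in ("genotyping_error", "dna_missing_rate", "zw_fixed_fraction",
                     "sexbias_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.compensation_scenario not in ("full", "none"):
            raise ValueError("compensation_scenario must be 'full' or 'none'")
        lo, hi = self.scaffold_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid scaffold_length_range")

    # one RNG stream per output artifact, derived from the master seed, so
    # each artifact can be regenerated independently of the others
    def rng(self, artifact: str) -> np.random.Generator:
        streams = ("genome", "coverage", "variants", "counts", "qpcr")
        if artifact not in streams:
            raise KeyError(artifact)
        child = np.random.SeedSequence(self.seed).spawn(len(streams))
        return np.random.default_rng(child[streams.index(artifact)])

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("scaffold_length_range", "transcript_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimGenome:
    """A simulated assembly: scaffolds with true classes, plus transcripts."""

    scaffolds: pd.DataFrame  # scaffold_id, length, true_class
    transcripts: pd.DataFrame  # transcript_id, scaffold_id, length, true_bias

    def __post_init__(self) -> None:
        known = set(self.scaffolds["scaffold_id"])
        if not set(self.transcripts["scaffold_id"]).issubset(known):
            raise ValueError("transcript placed on unknown scaffold")


def expected_inbreeding(generations: int) -> float:
    """Inbreeding coefficient after ``generations`` of full-sib mating.

    Uses the classical second-order recurrence
    ``F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4`` with ``F_0 = F_{-1} = 0``.
    Six generations give F = 0.734375, i.e. a ~73% reduction in
    heterozygosity.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    f_prev2, f_prev1 = 0.0, 0.0
    for _ in range(generations):
        f_prev2, f_prev1 = f_prev1, 0.25 * (1.0 + 2.0 * f_prev1 + f_prev2)
    return f_prev1


def simulate_genome(cfg: SimConfig) -> SimGenome:
    """Draw scaffold lengths/classes and place transcripts uniformly."""
    n_total = cfg.n_autosomal_scaffolds + cfg.n_z_scaffolds + cfg.n_youngz_scaffolds
    if n_total == 0:
        raise ValueError("empty genome: zero scaffolds of every class")
    rng = cfg.rng("genome")
    classes = np.array(
        ["A"] * cfg.n_autosomal_scaffolds
        + ["Z"] * cfg.n_z_scaffolds
        + ["youngZ"] * cfg.n_youngz_scaffolds
    )
    rng.shuffle(classes)
    lo, hi = cfg.scaffold_length_range
    lengths = rng.integers(lo, hi + 1, size=n_total)
    scaffolds = pd.DataFrame(
        {
            "scaffold_id": [f"scaffold{i:05d}" for i in range(n_total)],
            "length": lengths,
            "true_class": classes,
        }
    )

    # transcripts land on scaffolds with probability proportional to length
    probs = lengths / lengths.sum()
    t_scaf = rng.choice(scaffolds["scaffold_id"], size=cfg.n_transcripts, p=probs)
    tlo, thi = cfg.transcript_length_range
    t_len = rng.integers(tlo, thi + 1, size=cfg.n_transcripts)
    bias = np.array(["none"] * cfg.n_transcripts, dtype=object)
    n_biased = int(round(cfg.sexbias_fraction * cfg.n_transcripts))
    if n_biased:
        idx = rng.choice(cfg.n_transcripts, size=n_biased, replace=False)
        half = n_biased // 2
        bias[idx[:half]] = "male"
        bias[idx[half:]] = "female"
    transcripts = pd.DataFrame(
        {
            "transcript_id": [f"tr{i:05d}" for i in range(cfg.n_transcripts)],
            "scaffold_id": t_scaf,
            "length": t_len,
            "true_bias": bias,
        }
    )
    return SimGenome(scaffolds, transcripts)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def simulate_coverage(genome: SimGenome, cfg: SimConfig) -> pd.DataFrame:
    """Per-scaffold mean depth in each sex.

    Z-specific scaffolds get half dose in females (one Z instead of two);
    youngZ scaffolds co-assemble Z and W and keep full dose in both sexes.
    One log-normal factor per scaffold (CV = ``depth_dispersion``) models
    mappability/GC effects and applies to both sexes alike, so it cancels
    from the female:male ratio; the residual ratio noise is Poisson read
    sampling (100-bp reads), which shrinks with scaffold length and depth
    exactly as in real data.
    """
    if len(genome.scaffolds) == 0:
        raise ValueError("empty genome")
    rng = cfg.rng("coverage")
    n = len(genome.scaffolds)
    lengths = genome.scaffolds["length"].to_numpy()
    read_len = 100.0
    shared = _lognormal_factor(rng, cfg.depth_dispersion, n)
    dose_f = np.where(genome.scaffolds["true_class"] == "Z", 0.5, 1.0)

    def sampled_depth(mean_depth: np.ndarray) -> np.ndarray:
        if cfg.depth_dispersion == 0:  # noise-free closed form
            return mean_depth
        reads = rng.poisson(mean_depth * lengths / read_len)
        return reads * read_len / lengths

    depth_f = sampled_depth(cfg.depth_female * dose_f * shared)
    depth_m = sampled_depth(cfg.depth_male * shared)
    return pd.DataFrame(
        {
            "scaffold_id": genome.scaffolds["scaffold_id"],
            "length": genome.scaffolds["length"],
            "mean_depth_female": depth_f,
            "mean_depth_male": depth_m,
        }
    )


def sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    """Sample sheet for the variant table: RNA pools plus DNA individuals."""
    rows = []
    for i in range(cfg.pool_count_per_sex):
        rows.append((f"F_pool{i + 1}", "female", "RNA_pool"))
    for i in range(cfg.pool_count_per_sex):
        rows.append((f"M_pool{i + 1}", "male", "RNA_pool"))
    rows.append(("F_dna", "female", "DNA_individual"))
    rows.append(("M_dna", "male", "DNA_individual"))
    return pd.DataFrame(rows, columns=["sample", "sex", "material"])


def _intended_pool_call(alt_count: int, n_chrom: int) -> int:
    """Genotype a pool would be called as, given its true alt-allele count.

    Mirrors the downstream calling rule: homozygote if the alt fraction is
    <= 0.15 or >= 0.85, heterozygote if the minor fraction exceeds 0.30,
    otherwise the ambiguous band (NO_CALL).  Integer arithmetic keeps the
    boundaries exact (e.g. 3/10 must not "exceed" 30%).
    """
    if 20 * alt_count >= 17 * n_chrom:
        return HOM_ALT
    if 20 * alt_count <= 3 * n_chrom:
        return HOM_REF
    if 10 * min(alt_count, n_chrom - alt_count) > 3 * n_chrom:
        return HET
    return NO_CALL


def _depths_for_call(rng: np.random.Generator, call: int, total: int,
                     alt_fraction: float) -> tuple[int, int]:
    """Draw (ref, alt) read depths consistent with an intended genotype call.

    Depths are binomial around the expected allele fraction, rejection-
    sampled into the calling region of ``call`` so that with zero
    genotyping error the downstream call recovers the intended genotype
    exactly.  Sequencing error on homozygotes is 1%.
    """
    if total == 0:
        return 0, 0
    if call == HOM_REF:
        p, ok = 0.01, lambda alt: 20 * alt <= 3 * total
        fallback = 0
    elif call == HOM_ALT:
        p, ok = 0.99, lambda alt: 20 * alt >= 17 * total
        fallback = total
    elif call == HET:
        p, ok = 0.5, lambda alt: 10 * min(alt, total - alt) > 3 * total
        fallback = total // 2
    else:  # ambiguous band: conditioned likewise, so the downstream call is
        # NO_CALL with certainty and genotyping_error is the only call noise
        p = alt_fraction if 0.15 < alt_fraction < 0.85 else 0.25
        ok = (lambda alt: 3 * total < 20 * alt < 17 * total
              and 10 * min(alt, total - alt) <= 3 * total)
        fallback = int(round(0.25 * total)) if p <= 0.5 else int(round(0.75 * total))
    for _ in range(200):
        alt = int(rng.binomial(total, p))
        if ok(alt):
            return total - alt, alt
    # only reachable at tiny depth
    alt = fallback
    return total - alt, alt


def _flip(rng: np.random.Generator, call: int, error: float) -> int:
    """Apply genotyping error: with prob ``error`` flip het<->hom."""
    if call == NO_CALL or error == 0 or rng.random() >= error:
        return call
    if call == HET:
        return HOM_REF if rng.random() < 0.5 else HOM_ALT
    return HET


def simulate_variants(genome: SimGenome, cfg: SimConfig) -> pd.DataFrame:
    """Biallelic SNP table over RNA pools and DNA individuals.

    Returns a wide DataFrame with site metadata (scaffold_id, pos, ref,
    alt, qual, true_zw) and per-sample ``<sample>.ref`` / ``<sample>.alt``
    read-depth columns matching :func:`sample_sheet`.

    Young-Z scaffolds carry a configurable fraction of fixed Z/W
    differences (heterozygous in every female, homozygous in every male);
    all other SNPs are ordinary autosomal-style polymorphism with
    sex-independent genotypes.  DNA individuals come from an inbred line:
    their residual heterozygosity at polymorphic sites is scaled by
    (1 - F) with F from :func:`expected_inbreeding`.
    """
    if cfg.snps_per_kb <= 0:
        raise ValueError("snps_per_kb must be > 0")
    rng = cfg.rng("variants")
    sheet = sample_sheet(cfg)
    pools_f = sheet.loc[(sheet.sex == "female") & (sheet.material == "RNA_pool"), "sample"]
    pools_m = sheet.loc[(sheet.sex == "male") & (sheet.material == "RNA_pool"), "sample"]
    f_inbreeding = expected_inbreeding(cfg.inbreeding_generations)
    bases = np.array(list("ACGT"))
    n_chrom = 2 * cfg.pool_size

    rows: list[dict] = []
    for scaf_id, length, true_class in genome.scaffolds.itertuples(index=False):
        n_sites = rng.poisson(cfg.snps_per_kb * length / 1000.0)
        if n_sites == 0:
            continue
        positions = np.sort(rng.choice(np.arange(1, length + 1), size=min(n_sites, length),
                                       replace=False))
        for pos in positions:
            ref, alt = rng.choice(4, size=2, replace=False)
            is_zw = bool(true_class == "youngZ" and rng.random() < cfg.zw_fixed_fraction)
            row: dict = {
                "scaffold_id": scaf_id,
                "pos": int(pos),
                "ref": bases[ref],
                "alt": bases[alt],
                "qual": float(np.round(rng.uniform(30, 60), 1)),
                "true_zw": is_zw,
            }
            if is_zw:
                # fixed Z/W difference: W carries alt, so every ZW female pool
                # is 50% alt and every ZZ male pool is pure ref
                calls = {s: HET for s in pools_f} | {s: HOM_REF for s in pools_m}
                fracs = {s: 0.5 for s in pools_f} | {s: 0.0 for s in pools_m}
                dna_f_call, dna_m_call = HET, HOM_REF
            else:
                p_alt = rng.uniform(0.1, 0.9)
                calls, fracs = {}, {}
                for s in list(pools_f) + list(pools_m):
                    k = rng.binomial(n_chrom, p_alt)
                    fracs[s] = k / n_chrom
                    calls[s] = _intended_pool_call(k, n_chrom)
                # inbred DNA individuals under HWE with reduced heterozygosity
                p_het = 2 * p_alt * (1 - p_alt) * (1 - f_inbreeding)
                dna_calls = []
                for _ in range(2):
                    u = rng.random()
                    if u < p_het:
                        dna_calls.append(HET)
                    elif u < p_het + (1 - p_het) * p_alt:
                        dna_calls.append(HOM_ALT)
                    else:
                        dna_calls.append(HOM_REF)
                dna_f_call, dna_m_call = dna_calls

            for s in list(pools_f) + list(pools_m):
                depth_mean = cfg.depth_female if s.startswith("F") else cfg.depth_male
                total = int(rng.poisson(depth_mean))
                call = _flip(rng, calls[s], cfg.genotyping_error)
                r, a = _depths_for_call(rng, call, total, fracs[s])
                row[f"{s}.ref"], row[f"{s}.alt"] = r, a
            for s, call in (("F_dna", dna_f_call), ("M_dna", dna_m_call)):
                if rng.random() < cfg.dna_missing_rate:
                    row[f"{s}.ref"], row[f"{s}.alt"] = 0, 0
                    continue
                depth_mean = cfg.depth_female if s == "F_dna" else cfg.depth_male
                total = int(rng.poisson(depth_mean))
                call = _flip(rng, call, cfg.genotyping_error)
                frac = 0.5 if call == HET else (1.0 if call == HOM_ALT else 0.0)
                r, a = _depths_for_call(rng, call, total, frac)
                row[f"{s}.ref"], row[f"{s}.alt"] = r, a
            rows.append(row)
    return pd.DataFrame(rows)


def design_table(cfg: SimConfig) -> pd.DataFrame:
    """Canonical 2 tissues x 2 sexes x 2 replicates RNA-seq design."""
    rows = []
    for tissue in ("head", "gonad"):
        for sex in ("female", "male"):
            for rep in (1, 2):
                rows.append((f"{tissue}_{sex}_{rep}", tissue, sex, rep))
    return pd.DataFrame(rows, columns=["sample", "tissue", "sex", "replicate"])


def simulate_counts(genome: SimGenome, cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw RNA-seq count matrix (transcripts x 8 samples) plus design table.

    Baseline per-transcript expression is log-normal; expected counts are
    proportional to transcript length.  Under the "none" compensation
    scenario, female expression of Z-specific transcripts is halved (one
    gene copy, no compensatory up-regulation); under "full" it is equal.
    Sex-biased transcripts get ``sexbias_fold`` in their biased sex.
    Counts are gamma-Poisson with a single overdispersion parameter.
    """
    if len(genome.transcripts) == 0:
        raise ValueError("genome has no transcripts")
    rng = cfg.rng("counts")
    design = design_table(cfg)
    tr = genome.transcripts
    n = len(tr)
    scaf_class = genome.scaffolds.set_index("scaffold_id")["true_class"]
    on_z = (tr["scaffold_id"].map(scaf_class) == "Z").to_numpy()

    base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n)  # per-kb rate
    tissue_eff = {t: _lognormal_factor(rng, 0.25, n) for t in ("head", "gonad")}
    lib_factor = _lognormal_factor(rng, 0.1, len(design))

    female_z_dose = 0.5 if cfg.compensation_scenario == "none" else 1.0
    counts = np.empty((n, len(design)), dtype=np.int64)
    for j, (sample, tissue, sex, _rep) in enumerate(design.itertuples(index=False)):
        mu = base * (tr["length"].to_numpy() / 1000.0) * tissue_eff[tissue] * lib_factor[j]
        if sex == "female":
            mu = mu * np.where(on_z, female_z_dose, 1.0)
        biased_here = (tr["true_bias"] == sex).to_numpy()
        mu = mu * np.where(biased_here, cfg.sexbias_fold, 1.0)
        if cfg.count_dispersion > 0:
            shape = 1.0 / cfg.count_dispersion
            mu = rng.gamma(shape, mu * cfg.count_dispersion)
        counts[:, j] = rng.poisson(mu)
    mat = pd.DataFrame(counts, index=pd.Index(tr["transcript_id"], name="transcript_id"),
                       columns=design["sample"])
    return mat, design


def simulate_qpcr(cfg: SimConfig, n_z_loci: int = 10, n_autosomal_loci: int = 2,
                  n_individuals_per_sex: int = 3, cq_sd: float = 0.1) -> pd.DataFrame:
    """qPCR Cq table for Z-linked and autosomal target loci.

    Two autosomal reference genes normalize each individual.  Cq decreases
    by one cycle per doubling of template (100% efficiency): males carry
    two copies of a Z locus, females one.
    """
    rng = cfg.rng("qpcr")
    genes = (
        [(f"Z_locus{i + 1}", "target", {"male": 2, "female": 1}) for i in range(n_z_loci)]
        + [(f"A_locus{i + 1}", "target", {"male": 2, "female": 2}) for i in range(n_autosomal_loci)]
        + [(f"ref{i + 1}", "reference", {"male": 2, "female": 2}) for i in range(2)]
    )
    rows = []
    for gene, role, copies in genes:
        base = rng.uniform(18.0, 25.0)  # Cq at two copies
        for sex in ("female", "male"):
            for i in range(n_individuals_per_sex):
                cq = base - np.log2(copies[sex] / 2.0) + rng.normal(0.0, cq_sd)
                rows.append((f"{sex[0].upper()}{i + 1}", sex, gene, round(float(cq), 3), role))
    return pd.DataFrame(rows, columns=["individual", "sex", "gene", "cq", "role"])


def write_vcf(variants: pd.DataFrame, scaffolds: pd.DataFrame, sheet: pd.DataFrame,
              path: str | Path) -> None:
    """Write the variant table as minimal VCF 4.2 with per-sample AD and DP."""
    samples = list(sheet["sample"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Read depths for ref and alt alleles">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        for scaf_id, length in scaffolds[["scaffold_id", "length"]].itertuples(index=False):
            fh.write(f"##contig=<ID={scaf_id},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        col = {name: i for i, name in enumerate(variants.columns)}
        for row in variants.itertuples(index=False, name=None):
            fields = [row[col["scaffold_id"]], str(row[col["pos"]]), ".",
                      row[col["ref"]], row[col["alt"]],
                      f"{row[col['qual']]:g}", "PASS", ".", "AD:DP"]
            for s in samples:
                r, a = row[col[f"{s}.ref"]], row[col[f"{s}.alt"]]
                fields.append(f"{r},{a}:{r + a}")
            fh.write("\t".join(fields) + "\n")


def simulate_all(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every artifact and write the plain-text files the pipeline reads.

    Returns a dict of artifact name -> written path.  Identical configs
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(cfg)
    coverage = simulate_coverage(genome, cfg)
    variants = simulate_variants(genome, cfg)
    counts, design = simulate_counts(genome, cfg)
    qpcr = simulate_qpcr(cfg)
    sheet = sample_sheet(cfg)

    paths = {
        "coverage": outdir / "coverage.tsv",
        "vcf": outdir / "variants.vcf",
        "samples": outdir / "samples.tsv",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "transcript_map": outdir / "transcript_map.tsv",
        "truth": outdir / "truth.tsv",
        "qpcr": outdir / "qpcr_cq.tsv",
    }
    coverage.to_csv(paths["coverage"], sep="\t", index=False, float_format="%.4f")
    write_vcf(variants, genome.scaffolds, sheet, paths["vcf"])
    sheet.to_csv(paths["samples"], sep="\t", index=False)
    counts.to_csv(paths["counts"], sep="\t")
    design.to_csv(paths["design"], sep="\t", index=False)
    genome.transcripts.rename(columns={"transcript_id": "transcript"}).to_csv(
        paths["transcript_map"], sep="\t", index=False)
    genome.scaffolds[["scaffold_id", "true_class"]].to_csv(
        paths["truth"], sep="\t", index=False)
    qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    return paths
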