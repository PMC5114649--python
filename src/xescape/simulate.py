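"""Synthetic cohorts with the statistical structure of X-inactivation escape.

Every generator is deterministic given its ``seed`` and emits truth labels,
so downstream recovery rates are measurable. The generators emulate the
structure the analysis stages assume — escapee TSSs transcribed from both
X chromosomes (≈2x higher in females), an XIST-like female-only TSS,
female-intermediate/male-low promoter methylation at subject genes,
Xa-biased allelic read counts with designated Xi-biased loci, and a toy
diploid genome whose exact duplication defeats unique read mapping — not
the full covariance structure of real CAGE/450k/ChIP-seq data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    ExpressionMatrix,
    GenomicInterval,
    HetSite,
    MethylationDataset,
    PeakSet,
    SampleRecord,
    TSSRecord,
)

_BASES = np.array(list("ACGT"))


@dataclass
class CohortConfig:
    """Conditions for a sex-labelled CAGE-style expression cohort."""

    n_female: int = 100
    n_male: int = 100
    n_tss_x: int = 500
    n_tss_auto: int = 200
    n_escapee: int = 20
    escapee_female_fold: float = 2.0
    xist_like: bool = True
    n_categories: int = 10
    category_effect_sd: float = 0.3
    category_sex_bias: float = 0.0  # >0 skews category membership by sex
    noise_sd: float = 0.2
    baseline_log_mean_sd: tuple = (0.5, 0.4)
    repeat_fraction: float = 0.1
    xist_silenced_female_frac: float = 0.0  # emulates cancer lines losing the Xi
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_escapee > self.n_tss_x:
            raise ConfigError("n_escapee exceeds n_tss_x")
        if self.escapee_female_fold <= 0:
            raise ConfigError("escapee_female_fold must be > 0")
        if not 0 <= self.repeat_fraction <= 1:
            raise ConfigError("repeat_fraction must lie in [0, 1]")


@dataclass
class MethylationConfig:
    """Conditions for a chrX + autosomal promoter methylation panel.

    Class means follow the escape signature: subject-gene promoters are
    near-unmethylated in males (one active X) and intermediate in females
    (one methylated Xi copy averaged with the active copy); escapee
    promoters are low in both sexes; the XIST-like promoter is high in
    males and intermediate in females.

    The ``body`` class is the chrX background continuum away from CpG
    island promoters: per probe the Xa level is drawn from
    ``body_xa_range`` and the Xi level runs inversely
    (xi = intercept − slope·xa, clipped), i.e. the Xi is hypermethylated
    where the Xa is unmethylated and hypomethylated where it is
    methylated. The female beta averages the two X copies. This is what
    produces the positive chrX M–A trend that the robust regression fits,
    with escapee promoters deviating above it.
    """

    n_female: int = 60
    n_male: int = 60
    n_subject: int = 600
    n_escapee: int = 100
    n_body: int = 1800
    n_autosomal: int = 600
    n_auto_differential: int = 15
    subject_male_mean: float = 0.05
    subject_female_mean: float = 0.4
    escapee_mean: float = 0.05
    body_xa_range: tuple = (0.1, 0.95)
    xi_inversion_intercept: float = 0.9
    xi_inversion_slope: float = 0.85
    xist_male_mean: float = 0.9
    xist_female_mean: float = 0.5
    auto_diff_delta: float = 0.15
    concentration: float = 50.0  # Beta concentration; higher = less noise
    age_logit_effect: float = 0.005  # per year, autosomal probes
    stage_logit_effect: float = 0.05  # per stage unit, autosomal probes
    seed: int = 0


@dataclass
class AllelicSimConfig:
    """Conditions for per-(site, dataset) allelic read counts."""

    n_sites: int = 200
    n_datasets: int = 8
    frac_xa_biased: float = 0.8
    xi_biased_site_ids: tuple = ("site_xist", "site_firre")
    mean_total_reads: float = 60.0
    dispersion: float = 5.0
    xa_fraction_biased: float = 0.8
    xi_fraction_at_xi_sites: float = 0.97
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.xa_fraction_biased < 1:
            raise ConfigError("xa_fraction_biased must lie in (0, 1)")
        # 1.0 admissible: fully Xi-monoallelic sites (Ra identically 0)
        if not 0 < self.xi_fraction_at_xi_sites <= 1:
            raise ConfigError("xi_fraction_at_xi_sites must lie in (0, 1]")
        # 1.0 = no balanced sites: every regular site follows the Xa norm
        if not 0 < self.frac_xa_biased <= 1:
            raise ConfigError("frac_xa_biased must lie in (0, 1]")


# ------------------------------------------------------------- expression

def generate_cohort(config: CohortConfig):
    """Simulate an expression cohort.

    Returns ``(ExpressionMatrix, [TSSRecord], [SampleRecord], truth)`` where
    ``truth`` is a DataFrame indexed by tss_id with a ``tss_class`` column in
    {escapee, xist_like, null_x, autosomal}.

    Per-sample log10(TPM) at TSS k = baseline_k + Σ_t effect_{k,t}·member_t
    + sex effect + N(0, noise_sd), back-transformed to TPM. Escapee TSSs add
    log10(escapee_female_fold) in females; the XIST-like TSS is zero in males.
    Repeat flags are drawn only among null/autosomal TSSs so the planted
    escapees lie inside the retained testing universe.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_female + config.n_male
    sexes = np.array(["female"] * config.n_female + ["male"] * config.n_male)

    tss_ids, records, classes = [], [], []
    pos = 10_000
    esc_idx = rng.choice(config.n_tss_x, size=config.n_escapee, replace=False)
    esc_set = set(esc_idx.tolist())
    for i in range(config.n_tss_x):
        tid = f"tssX_{i:04d}"
        cls = "escapee" if i in esc_set else "null_x"
        strand = "+" if i % 2 == 0 else "-"
        records.append(
            TSSRecord(tid, GenomicInterval("chrX", pos, pos + 200, strand),
                      nearest_gene=f"XG{i:04d}")
        )
        tss_ids.append(tid)
        classes.append(cls)
        pos += 2000
    if config.xist_like:
        records.append(
            TSSRecord("tss_xist", GenomicInterval("chrX", pos, pos + 200, "+"),
                      nearest_gene="XIST_LIKE")
        )
        tss_ids.append("tss_xist")
        classes.append("xist_like")
    pos = 10_000
    for i in range(config.n_tss_auto):
        tid = f"tssA_{i:04d}"
        records.append(
            TSSRecord(tid, GenomicInterval("chr7", pos, pos + 200, "+"),
                      nearest_gene=f"AG{i:04d}")
        )
        tss_ids.append(tid)
        classes.append("autosomal")
        pos += 2000

    n_tss = len(tss_ids)
    mu, sd = config.baseline_log_mean_sd
    baseline = rng.normal(mu, sd, size=n_tss)

    # overlapping category memberships, optionally sex-skewed
    membership = np.zeros((n_samples, config.n_categories), dtype=int)
    for t in range(config.n_categories):
        p = np.full(n_samples, 0.2)
        if config.category_sex_bias > 0:
            shift = config.category_sex_bias if t % 2 == 0 else -config.category_sex_bias
            p = np.where(sexes == "female", np.clip(0.2 + shift, 0.01, 0.99),
                         np.clip(0.2 - shift, 0.01, 0.99))
        membership[:, t] = rng.random(n_samples) < p
    cat_effects = rng.normal(0.0, config.category_effect_sd,
                             size=(n_tss, config.n_categories))

    log_expr = (
        baseline[:, None]
        + cat_effects @ membership.T
        + rng.normal(0.0, config.noise_sd, size=(n_tss, n_samples))
    )
    is_female = (sexes == "female")[None, :]
    cls_arr = np.array(classes)
    esc_rows = (cls_arr == "escapee")[:, None]
    log_expr = log_expr + np.where(esc_rows & is_female,
                                   np.log10(config.escapee_female_fold), 0.0)
    values = np.power(10.0, log_expr)
    silenced_females = np.zeros(n_samples, dtype=bool)
    if config.xist_like:
        xist_row = tss_ids.index("tss_xist")
        values[xist_row, ~is_female[0]] = 0.0
        if config.xist_silenced_female_frac > 0:
            fem_idx = np.nonzero(is_female[0])[0]
            n_sil = int(round(config.xist_silenced_female_frac * fem_idx.size))
            sil = rng.choice(fem_idx, size=n_sil, replace=False)
            values[xist_row, sil] = 0.0
            silenced_females[sil] = True
    values = np.clip(values, 0.0, None)

    # repeat flags only outside the escapee/XIST truth classes
    for i, rec in enumerate(records):
        if classes[i] in ("null_x", "autosomal") and rng.random() < config.repeat_fraction:
            rec.repeat_overlap = True

    samples = [
        SampleRecord(
            sample_id=f"s{j:03d}",
            sex_label=sexes[j],
            categories=frozenset(f"cat{t}" for t in range(config.n_categories)
                                 if membership[j, t]),
            donor_id=f"d{j:03d}",
        )
        for j in range(n_samples)
    ]
    matrix = ExpressionMatrix(tss_ids, [s.sample_id for s in samples], values)
    truth = pd.DataFrame({"tss_class": classes}, index=pd.Index(tss_ids, name="tss_id"))
    truth.attrs["xist_silenced_samples"] = [
        samples[j].sample_id for j in np.nonzero(silenced_females)[0]
    ]
    return matrix, records, samples, truth


def category_membership(samples, categories=None) -> pd.DataFrame:
    """Binary sample x category membership matrix from SampleRecords."""
    if categories is None:
        categories = sorted(set().union(*(s.categories for s in samples)) or set())
    data = [[int(c in s.categories) for c in categories] for s in samples]
    return pd.DataFrame(data, index=[s.sample_id for s in samples], columns=list(categories))


# ------------------------------------------------------------- methylation

def _beta_draw(rng, mean, concentration, size):
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    return rng.beta(mean * concentration, (1 - mean) * concentration, size=size)


def generate_methylation(config: MethylationConfig):
    """Simulate promoter methylation with the escape signature.

    Returns ``(MethylationDataset, truth, [TSSRecord])``. Each probe sits at
    the 5' position of its own TSS so probe-to-TSS assignment is exercised.
    ``truth.probe_class`` is in {subject, escapee, xist_like, auto_null,
    auto_differential}. Autosomal probes carry small additive age and stage
    effects on the logit scale; the differential subset adds a sex shift.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_female + config.n_male
    sexes = np.array(["female"] * config.n_female + ["male"] * config.n_male)
    age = rng.uniform(40, 80, size=n_samples)
    stage = rng.integers(1, 5, size=n_samples)

    probe_ids, classes, positions, tss_records = [], [], {}, []

    def add(cls, chrom, idx, pos):
        pid = f"pr_{cls}_{idx:04d}"
        tid = f"tss_{cls}_{idx:04d}"
        probe_ids.append(pid)
        classes.append(cls)
        positions[pid] = GenomicInterval(chrom, pos, pos + 1)
        tss_records.append(
            TSSRecord(tid, GenomicInterval(chrom, pos, pos + 200, "+"),
                      nearest_gene=f"g_{cls}_{idx:04d}")
        )

    pos = 5_000
    for i in range(config.n_subject):
        add("subject", "chrX", i, pos)
        pos += 1500
    for i in range(config.n_escapee):
        add("escapee", "chrX", i, pos)
        pos += 1500
    for i in range(config.n_body):
        add("body", "chrX", i, pos)
        pos += 1500
    add("xist_like", "chrX", 0, pos)
    pos = 5_000
    for i in range(config.n_autosomal):
        cls = "auto_differential" if i < config.n_auto_differential else "auto_null"
        add(cls, "chr7", i, pos)
        pos += 1500

    female = sexes == "female"
    betas = np.empty((len(probe_ids), n_samples))
    auto_base = rng.uniform(0.15, 0.85, size=len(probe_ids))
    body_xa = rng.uniform(*config.body_xa_range, size=len(probe_ids))
    body_xi = np.clip(config.xi_inversion_intercept
                      - config.xi_inversion_slope * body_xa, 0.02, 0.95)
    for i, cls in enumerate(classes):
        if cls == "subject":
            mean = np.where(female, config.subject_female_mean, config.subject_male_mean)
        elif cls == "escapee":
            mean = np.full(n_samples, config.escapee_mean)
        elif cls == "body":
            mean = np.where(female, (body_xa[i] + body_xi[i]) / 2.0, body_xa[i])
        elif cls == "xist_like":
            mean = np.where(female, config.xist_female_mean, config.xist_male_mean)
        else:
            logit = np.log(auto_base[i] / (1 - auto_base[i]))
            logit = (logit
                     + config.age_logit_effect * (age - age.mean())
                     + config.stage_logit_effect * (stage - stage.mean()))
            if cls == "auto_differential":
                logit = logit + np.where(female, config.auto_diff_delta * 4, 0.0)
            mean = 1 / (1 + np.exp(-logit))
        betas[i] = _beta_draw(rng, mean, config.concentration, n_samples)

    sample_ids = [f"m{j:03d}" for j in range(n_samples)]
    covars = pd.DataFrame(
        {"sex": sexes, "age": age, "stage": stage},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    dataset = MethylationDataset(
        betas=pd.DataFrame(betas, index=probe_ids, columns=sample_ids),
        probe_positions=positions,
        covariates=covars,
    )
    truth = pd.DataFrame({"probe_class": classes}, index=pd.Index(probe_ids, name="probe_id"))
    return dataset, truth, tss_records


def generate_biallelic_peaksets(targets, background, n_female: int = 30,
                                n_male: int = 30,
                                detection_prob_range: tuple = (0.2, 0.6),
                                peak_halfwidth: int = 30, seed: int = 0) -> list:
    """Peak datasets under the bi-allelic detection model.

    Each dataset has a per-allele detection probability q; a TSS carries a
    peak if binding is detected on at least one active allele. Escapee
    targets have two active alleles in female cells but one in male cells,
    while background TSSs have one in both — so female datasets show a
    higher target overlap rate (probability 1-(1-q)^2 vs q) purely from
    measurements summing both X copies.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_female + n_male):
        sex = "female" if i < n_female else "male"
        q = rng.uniform(*detection_prob_range)
        ivs = []
        for t in targets:
            p = 1 - (1 - q) ** 2 if sex == "female" else q
            if rng.random() < p:
                ivs.append(GenomicInterval(t.chrom, max(0, t.five_prime - peak_halfwidth),
                                           t.five_prime + peak_halfwidth))
        for b in background:
            if rng.random() < q:
                ivs.append(GenomicInterval(b.chrom, max(0, b.five_prime - peak_halfwidth),
                                           b.five_prime + peak_halfwidth))
        out.append(PeakSet(ivs, dataset_id=f"ds{i:02d}", factor=f"TF{i:02d}",
                           cell=f"cell{i:02d}", cell_sex=sex, lab="lab0"))
    return out


# ------------------------------------------------------------- toy genome

@dataclass
class ToyGenome:
    """A toy haploid reference with one exact duplication and phased hets."""

    sequences: dict
    hets: list
    dup_source: GenomicInterval
    dup_target: GenomicInterval
    peaks: PeakSet
    hets_in_duplication: list = field(default_factory=list)


def generate_toy_genome(length: int = 6000, n_het: int = 8, dup_len: int = 400,
                        seed: int = 0, chrom: str = "chrX",
                        read_len: int = 36) -> ToyGenome:
    """Random sequence with an exact duplicated segment and phased het sites.

    Exactly one het (when ``dup_len`` > 0 and ``n_het`` >= 1) is planted
    inside the duplication source; the rest sit at least ``read_len`` bp
    away from both copies so their simulated reads map uniquely. Each het
    is covered by a ±50 bp peak so the read simulator visits all of them.
    """
    if dup_len >= length // 2:
        raise ConfigError("dup_len must be smaller than half the genome")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    src_start = length // 8
    dst_start = 5 * length // 8
    if dup_len > 0:
        seq[dst_start:dst_start + dup_len] = seq[src_start:src_start + dup_len]
    dup_src = GenomicInterval(chrom, src_start, src_start + max(dup_len, 1))
    dup_dst = GenomicInterval(chrom, dst_start, dst_start + max(dup_len, 1))

    forbidden = []
    if dup_len > 0:
        forbidden = [(src_start - read_len, src_start + dup_len + read_len),
                     (dst_start - read_len, dst_start + dup_len + read_len)]

    def clear(p: int) -> bool:
        return all(not (lo <= p < hi) for lo, hi in forbidden)

    het_positions = []
    if dup_len > 0 and n_het >= 1:
        het_positions.append(src_start + dup_len // 2)
    candidates = [p for p in range(read_len, length - read_len) if clear(p)]
    extra = rng.choice(len(candidates), size=n_het - len(het_positions), replace=False)
    het_positions.extend(candidates[i] for i in sorted(extra))
    het_positions = sorted(set(het_positions))

    hets, in_dup = [], []
    for i, p in enumerate(het_positions):
        ref = str(seq[p])
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        mat, pat = (ref, alt) if rng.random() < 0.5 else (alt, ref)
        site = HetSite(f"het_{i:02d}", chrom, p, ref, alt, maternal=mat, paternal=pat)
        hets.append(site)
        if dup_len > 0 and dup_src.contains(p):
            in_dup.append(site.site_id)

    peaks = PeakSet(
        intervals=[GenomicInterval(chrom, max(0, p - 50), min(length, p + 50))
                   for p in het_positions],
        dataset_id="toy_peaks",
    )
    return ToyGenome(
        sequences={chrom: "".join(seq)},
        hets=hets,
        dup_source=dup_src,
        dup_target=dup_dst,
        peaks=peaks,
        hets_in_duplication=in_dup,
    )


# ------------------------------------------------------------- allelic counts

def simulate_allelic_counts(config: AllelicSimConfig):
    """Simulate per-(site, dataset) Xa/Xi read counts.

    Returns ``(counts, truth)``: ``counts`` has columns site_id, dataset_id,
    factor, lab, ra, ri; ``truth`` maps site_id to direction in
    {xa_biased, xi_biased, balanced}. Totals are negative-binomial; the Xa
    read count is binomial with success probability 0.5 at balanced sites,
    ``xa_fraction_biased`` at Xa-biased sites and
    ``1 − xi_fraction_at_xi_sites`` at designated Xi-biased sites.
    """
    rng = np.random.default_rng(config.seed)
    regular_ids = [f"site_{i:03d}" for i in range(config.n_sites)]
    site_ids = list(config.xi_biased_site_ids) + regular_ids
    n_xa = int(round(config.frac_xa_biased * config.n_sites))
    directions = {}
    for sid in config.xi_biased_site_ids:
        directions[sid] = "xi_biased"
    shuffled = list(regular_ids)
    rng.shuffle(shuffled)
    for i, sid in enumerate(shuffled):
        directions[sid] = "xa_biased" if i < n_xa else "balanced"

    k = config.dispersion
    p_nb = k / (k + config.mean_total_reads)
    rows = []
    for d in range(config.n_datasets):
        dataset_id = f"ds_{d:02d}"
        factor, lab = f"TF{d % 4}", f"lab{d % 2}"
        totals = rng.negative_binomial(k, p_nb, size=len(site_ids))
        for sid, total in zip(site_ids, totals):
            f = {"xa_biased": config.xa_fraction_biased,
                 "xi_biased": 1.0 - config.xi_fraction_at_xi_sites,
                 "balanced": 0.5}[directions[sid]]
            ra = rng.binomial(total, f) if total > 0 else 0
            rows.append((sid, dataset_id, factor, lab, int(ra), int(total - ra)))
    counts = pd.DataFrame(rows, columns=["site_id", "dataset_id", "factor", "lab", "ra", "ri"])
    truth = pd.Series(directions, name="direction").rename_axis("site_id")
    return counts, truth
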