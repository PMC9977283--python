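"""Synthetic data generators with planted ground truth.

Every pipeline input can be generated here with stated distributions, planted
effects, and a seed, so the whole screen is testable without any external
download.  Each generator returns its dataset(s) plus a :class:`SimTruth`
recording what was planted; rerunning with identical arguments reproduces
identical output.

What the generators emulate (and what they do not) is documented in
``docs/methods.md``.  In brief:

* ``simulate_timecourse`` — an antisense-oligonucleotide knockdown-recovery
  experiment: the regulator protein drops to a nadir, plateaus, and recovers;
  tracking genes follow the protein trajectory linearly in log2 space with
  i.i.d. Gaussian noise, non-tracking genes are pure noise.
* ``simulate_constraint_table`` — a bimodal pLI distribution (most genes
  tolerant, a constrained minority near 1), with planted genes drawn from the
  constrained mode.
* ``simulate_study_panel`` — summary-level differential-expression results:
  per-gene log2FC estimates with known standard error, Wald p-values, and
  Benjamini-Hochberg adjustment within each study.  The planted robust gene
  is down in LOF models and up in GOF models.
* ``simulate_cells`` — negative-binomial single-cell counts for a focal gene
  pair coupled through a Gaussian copula targeting a per-class Spearman
  correlation, plus a marker gene separating excitatory from inhibitory
  neurons.
* ``simulate_fragments`` — Poisson fragment counts on a toy chromosome with
  planted per-window, per-genotype enrichment, and spike-in fragments on an
  exogenous genome.
* ``simulate_sections`` — objects placed uniformly across serial sections of
  one hemisphere, systematically sampled with random start and thinned by the
  dissector height and area sampling fractions.
* ``simulate_ct_table`` — qPCR Ct values with technical duplicates, a stable
  reference gene, and planted per-group fold-changes of the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .celltype import EXCITATORY, INHIBITORY
from .cutrun import FRAGMENT_COLUMNS, PRIMARY, SPIKE, GenomicWindow, SampleLibrary
from .screen import GOF, LOF, ProteinTrajectory, StudyDEResult, TimeCourse
from .stereology import SectionCounts

FRAGMENT_LENGTH_RANGE = (120, 180)  # plausible mononucleosome-free CUT&RUN range
SPIKE_CHROM = "ecoli"


@dataclass
class SimTruth:
    """Planted ground truth for one generated dataset."""

    tracking_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed slope
    robust_gene: str | None = None
    planted_rho: dict[str, float] = field(default_factory=dict)  # class -> Spearman target
    enriched_windows: dict[str, dict[str, float]] = field(default_factory=dict)
    # window id -> genotype -> fold enrichment
    true_total_cells: int | None = None
    constrained_genes: list[str] = field(default_factory=list)
    fold_change_by_group: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# time course


def knockdown_recovery_curve(
    timepoints: np.ndarray,
    nadir_depth: float = -2.5,
    nadir_start_frac: float = 0.25,
    nadir_end_frac: float = 0.55,
) -> np.ndarray:
    """Piecewise-linear protein trajectory: drop, plateau at the nadir, recover.

    Fractions are positions along the (first, last) timepoint span.  The
    plateau reflects the sustained phase of a bolus knockdown before washout.
    """
    t = np.asarray(timepoints, dtype=float)
    t0, t1 = t[0], t[-1]
    a = t0 + nadir_start_frac * (t1 - t0)
    b = t0 + nadir_end_frac * (t1 - t0)
    return np.interp(t, [t0, a, b, t1], [0.0, nadir_depth, nadir_depth, 0.0])


def simulate_timecourse(
    n_genes: int = 100,
    n_tracking: int = 6,
    timepoints: tuple[float, ...] = (2, 4, 6, 8, 10, 12, 14, 16),
    slope_range: tuple[float, float] = (0.5, 1.5),
    noise_sd: float = 0.1,
    seed: int = 0,
    nadir_depth: float = -2.5,
) -> tuple[TimeCourse, ProteinTrajectory, SimTruth]:
    """Knockdown-recovery time course with planted protein-tracking genes.

    Tracking genes satisfy ``geneFC(t) = slope * proteinFC(t) + N(0, noise_sd)``
    with |slope| drawn from ``slope_range`` and a random sign; non-tracking
    genes are i.i.d. ``N(0, noise_sd)`` across timepoints.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if n_tracking > n_genes:
        raise ValueError("n_tracking cannot exceed n_genes")
    tps = np.asarray(timepoints, dtype=float)
    if len(tps) < 4:
        raise ValueError("need >=4 timepoints")
    if len(np.unique(tps)) != len(tps):
        raise ValueError("duplicate timepoints")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    prot = knockdown_recovery_curve(tps, nadir_depth=nadir_depth)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    tracking = list(rng.choice(genes, size=n_tracking, replace=False))

    mat = rng.normal(0.0, noise_sd, size=(n_genes, len(tps)))
    slopes: dict[str, float] = {}
    lo, hi = slope_range
    for g in tracking:
        slope = float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
        slopes[g] = slope
        mat[genes.index(g)] += slope * prot

    tc = TimeCourse(pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=tps))
    traj = ProteinTrajectory(pd.Series(prot, index=tps, name="protein_log2fc"))
    return tc, traj, SimTruth(tracking_genes=slopes)


def simulate_constraint_table(
    gene_ids: list[str],
    constrained_genes: list[str] | None = None,
    frac_high: float = 0.15,
    seed: int = 0,
) -> tuple[pd.Series, SimTruth]:
    """Bimodal pLI table: planted genes ~ U(0.92, 1); background genes are a
    15%/85% mixture of Beta(9, 1) (constrained mode) and Beta(1, 9) (tolerant
    mode), emulating the bimodality of observed constraint scores."""
    constrained = list(constrained_genes or [])
    unknown = set(constrained) - set(gene_ids)
    if unknown:
        raise ValueError(f"constrained genes absent from gene list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    pli = pd.Series(index=pd.Index(gene_ids, name="gene"), dtype=float, name="pLI")
    for g in gene_ids:
        if g in constrained:
            pli[g] = rng.uniform(0.92, 1.0)
        elif rng.random() < frac_high:
            pli[g] = rng.beta(9, 1)
        else:
            pli[g] = rng.beta(1, 9)
    return pli, SimTruth(constrained_genes=constrained)


# ---------------------------------------------------------------------------
# cross-study DE panel


def simulate_study_panel(
    n_studies: int = 20,
    model_classes: list[str] | None = None,
    target_effect: float = 1.0,
    se: float = 0.2,
    n_genes: int = 50,
    seed: int = 0,
    robust_gene: str = "gene0000",
) -> tuple[list[StudyDEResult], SimTruth]:
    """Summary-level DE panel with one planted cross-study robust gene.

    Per study the planted gene's estimated log2FC is ``N(-effect, se)`` in LOF
    models and ``N(+effect, se)`` in GOF models; null genes are ``N(0, se)``.
    p-values are two-sided normal on estimate/se, BH-adjusted within study.
    ``n_genes`` defaults to a candidate-shortlist-sized universe (the tables
    consumed downstream carry the screened gene set, not a whole genome; BH
    adjustment is performed within that universe).
    """
    if model_classes is None:
        # a panel dominated by loss-of-function models with a gain-of-function
        # minority, mirroring the usual composition of such collections
        model_classes = [LOF] * 14 + [GOF] * 6
    if not model_classes:
        raise ValueError("model class list is empty")
    if len(model_classes) != n_studies:
        raise ValueError("n_studies must equal len(model_classes)")
    if target_effect < 0:
        raise ValueError("target_effect must be >= 0")
    bad = set(model_classes) - {LOF, GOF}
    if bad:
        raise ValueError(f"unknown model classes: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    if robust_gene not in genes:
        raise ValueError("robust_gene must be one of the generated gene ids")
    panel = []
    for k, mc in enumerate(model_classes):
        lfc = rng.normal(0.0, se, size=n_genes)
        sign = -1.0 if mc == LOF else 1.0
        lfc[genes.index(robust_gene)] = rng.normal(sign * target_effect, se)
        p = 2 * stats.norm.sf(np.abs(lfc) / se)
        padj = stats.false_discovery_control(p, method="bh")
        table = pd.DataFrame(
            {"log2fc": lfc, "padj": padj}, index=pd.Index(genes, name="gene")
        )
        panel.append(
            StudyDEResult(
                study_id=f"study{k + 1:02d}",
                model_class=mc,
                table=table,
                tissue="brain",
            )
        )
    return panel, SimTruth(robust_gene=robust_gene)


# ---------------------------------------------------------------------------
# single-cell counts


def _copula_nb_pair(
    rng: np.random.Generator,
    n: int,
    rho_target: float,
    nb_mean: float,
    nb_dispersion: float,
) -> np.ndarray:
    """NB marginal pair coupled by a Gaussian copula targeting Spearman rho.

    Latent Pearson correlation from the closed relation
    ``rho_S = (6/pi) * arcsin(r/2)``; residual attenuation from NB
    discretization is accepted (small at the default marginals).
    """
    r = 2.0 * np.sin(np.pi * rho_target / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    u = stats.norm.cdf(z)
    if nb_dispersion > 0:
        shape = 1.0 / nb_dispersion
        x = stats.nbinom.ppf(u, shape, shape / (shape + nb_mean))
    else:
        x = stats.poisson.ppf(u, nb_mean)
    return x.astype(np.int64)


def simulate_cells(
    n_cells_per_class: dict[str, int] | None = None,
    target_rho: float | dict[str, float] = 0.7,
    marker_gene: str = "Slc17a7",
    gene_a: str = "Gdf11",
    gene_b: str = "Mecp2",
    nb_mean: float = 4.0,
    nb_dispersion: float = 0.3,
    frac_excitatory: float = 0.6,
    marker_min: int = 5,
    n_background_genes: int = 7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Single-cell counts (genes x cells) with a planted focal-pair correlation.

    Per annotated class, the focal gene pair is drawn from NB marginals coupled
    through a Gaussian copula targeting ``target_rho`` (scalar or per-class
    mapping).  Neurons additionally carry the marker gene: a ``frac_excitatory``
    share is guaranteed >= ``marker_min`` counts (threshold + Poisson
    overshoot), the rest are capped below it; non-neurons get low marker counts.
    """
    if n_cells_per_class is None:
        n_cells_per_class = {
            "astrocyte": 1500,
            "microglia": 1000,
            "neuron": 3000,
            "oligodendrocyte": 1000,
        }
    if nb_dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    classes = sorted(n_cells_per_class)
    rho_by_class = (
        {c: float(target_rho) for c in classes}
        if np.isscalar(target_rho)
        else {c: float(target_rho[c]) for c in classes}
    )
    for c, r in rho_by_class.items():
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target_rho for {c!r} outside [-1, 1]")

    rng = np.random.default_rng(seed)
    cell_ids, labels, blocks = [], [], []
    for c in classes:
        n = n_cells_per_class[c]
        pair = _copula_nb_pair(rng, n, rho_by_class[c], nb_mean, nb_dispersion)
        if c == "neuron":
            exc = rng.random(n) < frac_excitatory
            marker = np.where(
                exc,
                marker_min + rng.poisson(5.0, n),
                np.minimum(rng.poisson(0.5, n), marker_min - 1),
            )
        else:
            marker = np.minimum(rng.poisson(0.2, n), marker_min - 1)
        blocks.append(np.column_stack([pair, marker]))
        cell_ids += [f"{c}_{i:05d}" for i in range(n)]
        labels += [c] * n
    focal = np.vstack(blocks).T  # 3 x total cells

    genes = [gene_a, gene_b, marker_gene]
    total = focal.shape[1]
    rows = [focal[0], focal[1], focal[2]]
    for j in range(n_background_genes):
        genes.append(f"bg{j:03d}")
        rows.append(rng.poisson(rng.uniform(0.5, 6.0), total))
    counts = pd.DataFrame(
        np.vstack(rows).astype(np.int64),
        index=pd.Index(genes, name="gene"),
        columns=pd.Index(cell_ids, name="cell"),
    )
    annotation = pd.Series(labels, index=counts.columns, name="class")
    return counts, annotation, SimTruth(planted_rho=rho_by_class)


# ---------------------------------------------------------------------------
# CUT&RUN fragments


def simulate_fragments(
    windows: list[GenomicWindow],
    genotypes: dict[str, str],
    background_rate: float = 0.5,
    enrichment: dict[str, dict[str, float]] | None = None,
    spike_mean: float = 5000.0,
    chrom: str = "chr1",
    chrom_length: int = 1_000_000,
    antibody: str = "MeCP2",
    seed: int = 0,
) -> tuple[pd.DataFrame, list[SampleLibrary], SimTruth]:
    """Fragment intervals with planted per-window, per-genotype enrichment.

    ``background_rate`` is fragments per kb per sample.  Within each truth
    window the fragment count is Poisson(background * width_kb * fold) where
    ``fold = enrichment[window_id][genotype]`` (default 1); between windows it
    is Poisson(background * width_kb).  Spike-genome fragments are
    Poisson(spike_mean) per sample; all lengths are uniform in [120, 180] bp.
    Truth windows must not overlap (rejected to keep the planted truth
    unambiguous).
    """
    if spike_mean <= 0:
        raise ValueError("spike_mean must be > 0")
    enrichment = enrichment or {}
    for wid, per_geno in enrichment.items():
        for fold in per_geno.values():
            if fold < 0:
                raise ValueError(f"window {wid}: enrichment must be >= 0")
    ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"truth windows overlap: {a.window_id} and {b.window_id}")
    for w in ordered:
        if w.chrom != chrom or w.end > chrom_length:
            raise ValueError(f"window {w.window_id} outside simulated chromosome")

    # partition [0, chrom_length) into windows and gaps
    regions: list[tuple[int, int, str | None]] = []
    pos = 0
    for w in ordered:
        if w.start > pos:
            regions.append((pos, w.start, None))
        regions.append((w.start, w.end, w.window_id))
        pos = w.end
    if pos < chrom_length:
        regions.append((pos, chrom_length, None))

    rng = np.random.default_rng(seed)
    lmin, lmax = FRAGMENT_LENGTH_RANGE
    recs: list[tuple[str, int, int, str, str]] = []
    for sample in sorted(genotypes):
        geno = genotypes[sample]
        for rstart, rend, wid in regions:
            width_kb = (rend - rstart) / 1000.0
            fold = enrichment.get(wid, {}).get(geno, 1.0) if wid else 1.0
            n = rng.poisson(background_rate * width_kb * fold)
            if n == 0:
                continue
            starts = rng.integers(rstart, rend, size=n)
            lengths = rng.integers(lmin, lmax + 1, size=n)
            for s, ln in zip(starts, lengths):
                recs.append((chrom, int(s), int(s + ln), sample, PRIMARY))
        n_spike = rng.poisson(spike_mean)
        sp_starts = rng.integers(0, 4_600_000, size=n_spike)
        sp_lengths = rng.integers(lmin, lmax + 1, size=n_spike)
        for s, ln in zip(sp_starts, sp_lengths):
            recs.append((SPIKE_CHROM, int(s), int(s + ln), sample, SPIKE))

    frags = pd.DataFrame(recs, columns=FRAGMENT_COLUMNS)
    libs = []
    for sample in sorted(genotypes):
        sub = frags[frags["sample"] == sample]
        libs.append(
            SampleLibrary(
                sample=sample,
                genotype=genotypes[sample],
                antibody=antibody,
                primary_count=int((sub["genome"] == PRIMARY).sum()),
                spike_count=int((sub["genome"] == SPIKE).sum()),
            )
        )
    return frags, libs, SimTruth(enriched_windows=enrichment)


# ---------------------------------------------------------------------------
# stereology sections


def simulate_sections(
    true_total: int = 12000,
    n_sections_total: int = 60,
    ssf: float = 1 / 6,
    t: float = 40.0,
    h: float = 40.0,
    asf: float = 1.0,
    section_area_um2: float = 150_000.0,
    seed: int = 0,
) -> tuple[SectionCounts, np.ndarray, SimTruth]:
    """Uniform objects over one hemisphere's sections, systematically sampled.

    ``true_total`` is the bilateral (whole-brain) count; half of it is placed
    uniformly across ``n_sections_total`` sections of the sectioned
    hemisphere.  Every 1/ssf-th section is sampled with a random start, and
    counted objects within a sampled section are thinned Binomial with
    probability ``(h/t) * asf``.  Returns the section counts, the sampled
    section areas (for the density denominator), and the truth.
    """
    if true_total < 0:
        raise ValueError("true_total must be >= 0")
    if not 0 < ssf <= 1:
        raise ValueError("ssf must lie in (0, 1]")
    period = 1.0 / ssf
    if abs(period - round(period)) > 1e-9:
        raise ValueError("ssf must equal 1/k for integer k (systematic sampling)")
    period = int(round(period))
    if not 0 < h <= t:
        raise ValueError("need 0 < h <= t")
    if not 0 < asf <= 1:
        raise ValueError("asf must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    hemi_total = true_total // 2
    per_section = rng.multinomial(hemi_total, np.full(n_sections_total, 1.0 / n_sections_total))
    start = int(rng.integers(period))
    sampled = np.arange(start, n_sections_total, period)
    thin = (h / t) * asf
    q = rng.binomial(per_section[sampled], thin)
    sections = SectionCounts(q=q, t=t, h=h, asf=asf, ssf=ssf)
    areas = np.full(len(sampled), section_area_um2)
    return sections, areas, SimTruth(true_total_cells=true_total)


# ---------------------------------------------------------------------------
# qPCR Ct table


def simulate_ct_table(
    fold_change_by_group: dict[str, float] | None = None,
    control_group: str = "WT",
    n_replicates: int = 4,
    target: str = "Gdf11",
    reference: str = "Ppia",
    ref_ct: float = 20.0,
    base_delta_ct: float = 5.0,
    biological_sd: float = 0.15,
    technical_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """qPCR wells in technical duplicate with planted group fold-changes.

    The target's true dCt in group g is ``base_delta_ct - log2(fold)`` where
    ``fold = fold_change_by_group[g]`` (control fold is 1 by construction).
    Biological scatter perturbs each sample's dCt; technical scatter perturbs
    each well.
    """
    if fold_change_by_group is None:
        fold_change_by_group = {control_group: 1.0, "KO": 0.5, "TG": 2.0}
    if control_group not in fold_change_by_group:
        raise ValueError("control group missing from fold_change_by_group")
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(fold_change_by_group):
        fold = fold_change_by_group[group]
        for i in range(n_replicates):
            sample = f"{group}_{i + 1}"
            ref_mu = ref_ct + rng.normal(0.0, biological_sd)
            dct = base_delta_ct - np.log2(fold) + rng.normal(0.0, biological_sd)
            for gene, mu in ((reference, ref_mu), (target, ref_mu + dct)):
                for _ in range(2):  # technical duplicate
                    rows.append(
                        {
                            "gene": gene,
                            "sample": sample,
                            "group": group,
                            "ct": mu + rng.normal(0.0, technical_sd),
                            "detected": True,
                        }
                    )
    table = pd.DataFrame(rows, columns=["gene", "sample", "group", "ct", "detected"])
    return table, SimTruth(fold_change_by_group=dict(fold_change_by_group))
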