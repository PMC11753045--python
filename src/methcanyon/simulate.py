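"""Synthetic WGBS / methylation-array cohort generation with planted truth.

The generator emulates the data regime of a two-cohort tumor/normal WGBS
study with an added array-profiled cohort:

* CpG sites follow a Poisson (exponential-gap) process at ~100-bp mean
  spacing, five-fold denser inside CpG islands;
* per-CpG coverage is negative binomial with mean 25x (moderate
  overdispersion), methylated counts are Beta-Binomial around a local mean
  methylation mu;
* the local mean is high in open sea (0.75), low at CpG islands, shifted in
  tumor groups (global hypomethylation, island hypermethylation), near zero
  inside planted methylation canyons (with a 200-bp linear border ramp so
  boundary-recovery error is measurable), and promoter-specific where
  promoter effects are planted;
* the array-like cohort observes beta values only at a sparse probe subset
  (~2% of CpGs, enriched at promoters) and can be passed through a
  monotone logistic compression toward 0.5 emulating a platform batch
  effect;
* everything planted is recorded in a :class:`TruthSet` for recovery
  scoring.

In the degenerate infinite-precision limit (``bb_precision = inf``) the
methylated count is the deterministic rounding ``round(coverage * mu)``.

All randomness flows from a single seed through ``numpy`` SeedSequence
spawning, so regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotation import promoter_windows
from .io import records_from_arrays

_EPS = 1e-6


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic methylome.

    Defaults reflect the emulated study: 25x planned coverage, ~100-bp CpG
    spacing, 0.75 open-sea methylation, near-zero (0.02) canyon
    methylation, a 7-normal / 9-tumor WGBS design and an 18-sample
    array cohort.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length_bp: int = 5_000_000
    mean_cpg_spacing_bp: float = 100.0
    island_count: int = 40
    island_length_bp: int = 1000
    island_density_factor: float = 5.0
    gene_count: int = 60
    gene_length_range_bp: tuple = (2_000, 20_000)
    repeat_count: int = 100
    repeat_length_bp: int = 300
    mean_coverage: float = 25.0
    coverage_dispersion: float = 0.2
    bb_precision: float = 30.0
    background_meth: float = 0.75
    island_meth: float = 0.15
    canyon_meth: float = 0.02
    canyon_ramp_bp: int = 200
    # cohort design
    group_sizes: dict = field(default_factory=lambda: {"NAT": 7, "EOCRC": 9})
    tumor_groups: tuple = ("EOCRC", "LOCRC")
    tumor_background_delta: float = -0.10
    tumor_island_delta: float = 0.25
    # planted features
    n_canyons: int = 20
    canyon_length_range_bp: tuple = (4_000, 10_000)
    canyon_groups: list | None = None  # one tuple of group names per canyon; None = all
    n_dmp_sites: int = 0
    dmp_delta: float = 0.4
    n_pdmr: int = 0
    pdmr_delta: float = 0.3
    # array-like cohort
    array_size: int = 0
    array_group: str = "TCGA"
    array_precision: float = 50.0
    batch_shift: float = 1.0  # logistic compression factor; 1.0 = identity
    probe_fraction: float = 0.02
    probes_per_promoter: int = 3

    def validate(self) -> None:
        if self.mean_cpg_spacing_bp <= 0 or self.mean_coverage <= 0:
            raise ValueError("spacing and coverage must be positive")
        if self.coverage_dispersion <= 0 or self.bb_precision <= 0:
            raise ValueError("dispersion and precision must be positive")
        for p in (self.background_meth, self.island_meth, self.canyon_meth):
            if not 0.0 <= p <= 1.0:
                raise ValueError("methylation levels must lie in [0, 1]")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("negative group size")
        if self.island_count * self.island_length_bp > self.n_chroms * self.chrom_length_bp:
            raise ValueError("islands total more bp than the genome (infeasible packing)")


@dataclass
class Annotation:
    chrom_sizes: dict
    cpg_positions: dict  # chrom -> sorted int array
    islands: pd.DataFrame
    genes: pd.DataFrame  # gene, chrom, start, end, tss, strand
    repeats: pd.DataFrame
    probes: pd.DataFrame  # chrom, pos

    @property
    def promoters(self) -> pd.DataFrame:
        return promoter_windows(self.genes)

    def n_cpgs(self) -> int:
        return int(sum(len(p) for p in self.cpg_positions.values()))


@dataclass
class TruthSet:
    """Everything the generator planted, for recovery scoring."""

    canyons: pd.DataFrame  # chrom, start, end, name, groups (tuple)
    dmp_sites: pd.DataFrame  # chrom, pos, mu_normal, mu_tumor
    pdmr_promoters: pd.DataFrame  # gene, base_mean, wgbs_mean, array_mean, delta, direction
    promoter_base_means: pd.Series | None = None  # per-gene shared base mean


def _slot_intervals(rng, chrom_length, count, lengths, margin=2000):
    """Place ``count`` non-overlapping intervals by jittering one per equal slot."""
    if count == 0:
        return np.empty((0, 2), dtype=np.int64)
    slot = chrom_length // count
    out = []
    for i, L in enumerate(lengths):
        L = int(min(L, slot - 2 * margin)) if slot > 2 * margin + 1 else int(min(L, slot - 2))
        L = max(L, 2)
        lo = i * slot + margin if slot > 2 * margin + L else i * slot
        hi = (i + 1) * slot - margin - L if slot > 2 * margin + L else (i + 1) * slot - L
        start = int(rng.integers(lo, max(hi, lo + 1)))
        out.append((start, start + L))
    return np.array(out, dtype=np.int64)


def _round_robin(count, n_chroms):
    per = [count // n_chroms] * n_chroms
    for i in range(count % n_chroms):
        per[i] += 1
    return per


def simulate_annotation(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Generate the genome annotation: CpG positions (Poisson spacing,
    denser inside islands), islands, genes with TSS/strand on both strands,
    repeats, and the sparse array probe subset."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    chroms = [f"chr{i+1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: config.chrom_length_bp for c in chroms}
    L = config.chrom_length_bp
    if config.island_count and config.island_length_bp * max(_round_robin(config.island_count, config.n_chroms)) > L:
        raise ValueError("islands total more bp than a chromosome (infeasible packing)")

    islands_rows, genes_rows, repeats_rows = [], [], []
    per_isl = _round_robin(config.island_count, config.n_chroms)
    per_gene = _round_robin(config.gene_count, config.n_chroms)
    per_rep = _round_robin(config.repeat_count, config.n_chroms)
    gene_id = 0
    for ci, chrom in enumerate(chroms):
        iv = _slot_intervals(rng, L, per_isl[ci], [config.island_length_bp] * per_isl[ci], margin=500)
        for s, e in iv:
            islands_rows.append((chrom, int(s), int(e)))
        glens = rng.integers(config.gene_length_range_bp[0], config.gene_length_range_bp[1] + 1, per_gene[ci])
        gv = _slot_intervals(rng, L, per_gene[ci], glens, margin=2000)
        strands = rng.choice(["+", "-"], size=per_gene[ci])
        for (s, e), strand in zip(gv, strands):
            tss = int(s) if strand == "+" else int(e)
            genes_rows.append((f"G{gene_id:05d}", chrom, int(s), int(e), tss, strand))
            gene_id += 1
        rv = _slot_intervals(rng, L, per_rep[ci], [config.repeat_length_bp] * per_rep[ci], margin=0)
        for s, e in rv:
            repeats_rows.append((chrom, int(s), int(e)))
    islands = pd.DataFrame(islands_rows, columns=["chrom", "start", "end"])
    genes = pd.DataFrame(genes_rows, columns=["gene", "chrom", "start", "end", "tss", "strand"])
    # give six genes the canonical CIMP marker names so the panel check runs
    from .annotation import cimp_panel

    panel = cimp_panel()
    if len(genes) >= len(panel):
        genes.loc[genes.index[: len(panel)], "gene"] = panel
    repeats = pd.DataFrame(repeats_rows, columns=["chrom", "start", "end"])

    cpg_positions = {}
    for chrom in chroms:
        isl = islands[islands["chrom"] == chrom].sort_values("start")
        # alternating sea/island segments with their local mean spacing
        bounds = [0]
        dense = []
        for row in isl.itertuples(index=False):
            bounds += [row.start, row.end]
            dense += [False, True]
        bounds.append(L)
        dense.append(False)
        pos_parts = []
        for (b0, b1), is_island in zip(zip(bounds[:-1], bounds[1:]), dense):
            seg_len = b1 - b0
            if seg_len <= 0:
                continue
            sp = config.mean_cpg_spacing_bp / (config.island_density_factor if is_island else 1.0)
            n_draw = int(seg_len / sp * 1.35) + 20
            gaps = rng.exponential(sp, n_draw)
            p = b0 + np.cumsum(gaps)
            while len(p) and p[-1] < b1:  # rare undershoot: extend
                extra = p[-1] + np.cumsum(rng.exponential(sp, n_draw))
                p = np.concatenate([p, extra])
            pos_parts.append(p[p < b1].astype(np.int64))
        pos = np.unique(np.concatenate(pos_parts)) if pos_parts else np.empty(0, dtype=np.int64)
        cpg_positions[chrom] = pos[(pos >= 0) & (pos < L - 1)]

    probes = _pick_probes(config, rng, chroms, cpg_positions, genes)
    return Annotation(chrom_sizes, cpg_positions, islands, genes, repeats, probes)


def _pick_probes(config, rng, chroms, cpg_positions, genes) -> pd.DataFrame:
    """Array-like probe subset: a few CpGs per promoter plus random
    background, ~probe_fraction of all sites."""
    rows = []
    windows = promoter_windows(genes) if len(genes) else pd.DataFrame(columns=["chrom", "start", "end"])
    chosen = {c: np.zeros(len(cpg_positions[c]), dtype=bool) for c in chroms}
    for row in windows.itertuples(index=False):
        pos = cpg_positions.get(row.chrom)
        if pos is None or len(pos) == 0:
            continue
        lo, hi = np.searchsorted(pos, [row.start, row.end])
        if hi <= lo:
            continue
        k = min(config.probes_per_promoter, hi - lo)
        picks = lo + np.unique(np.linspace(0, hi - lo - 1, k).round().astype(int))
        chosen[row.chrom][picks] = True
    total = sum(len(p) for p in cpg_positions.values())
    target = int(config.probe_fraction * total)
    already = int(sum(m.sum() for m in chosen.values()))
    if target > already and total > already:
        # distribute the remainder uniformly over unchosen sites
        remaining = target - already
        pool = [(c, i) for c in chroms for i in np.flatnonzero(~chosen[c])]
        idx = rng.choice(len(pool), size=min(remaining, len(pool)), replace=False)
        for j in idx:
            c, i = pool[j]
            chosen[c][i] = True
    for c in chroms:
        for p in cpg_positions[c][chosen[c]]:
            rows.append((c, int(p)))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def plant_truth(config: SimulationConfig, annotation: Annotation, rng: np.random.Generator) -> TruthSet:
    """Draw the planted canyons, DMP sites and promoter effects."""
    groups = tuple(config.group_sizes.keys())
    canyon_rows = []
    if config.n_canyons:
        per = _round_robin(config.n_canyons, config.n_chroms)
        ci = 0
        for k, chrom in enumerate(annotation.chrom_sizes):
            lengths = rng.integers(
                config.canyon_length_range_bp[0], config.canyon_length_range_bp[1] + 1, per[k]
            )
            iv = _slot_intervals(rng, annotation.chrom_sizes[chrom], per[k], lengths, margin=5000)
            for s, e in iv:
                present = (
                    tuple(config.canyon_groups[ci])
                    if config.canyon_groups is not None
                    else groups
                )
                canyon_rows.append((chrom, int(s), int(e), f"canyon{ci:03d}", present))
                ci += 1
    canyons = pd.DataFrame(canyon_rows, columns=["chrom", "start", "end", "name", "groups"])

    dmp_rows = []
    if config.n_dmp_sites:
        chrom = next(iter(annotation.cpg_positions))
        pos = annotation.cpg_positions[chrom]
        free = np.ones(len(pos), dtype=bool)
        for row in canyons[canyons["chrom"] == chrom].itertuples(index=False):
            lo, hi = np.searchsorted(pos, [row.start - 500, row.end + 500])
            free[lo:hi] = False
        idx = rng.choice(np.flatnonzero(free), size=config.n_dmp_sites, replace=False)
        for i in np.sort(idx):
            mu_n = config.background_meth
            mu_t = float(np.clip(mu_n + config.dmp_delta * rng.choice([-1.0, 1.0]), _EPS, 1 - _EPS))
            dmp_rows.append((chrom, int(pos[i]), mu_n, mu_t))
    dmp_sites = pd.DataFrame(dmp_rows, columns=["chrom", "pos", "mu_normal", "mu_tumor"])

    base_means = None
    pdmr_rows = []
    if config.n_pdmr or config.array_size:
        gene_names = annotation.genes["gene"].to_numpy()
        low = rng.random(len(gene_names)) < 0.4
        base = np.where(
            low, rng.uniform(0.05, 0.20, len(gene_names)), rng.uniform(0.30, 0.85, len(gene_names))
        )
        base_means = pd.Series(base, index=gene_names)
        if config.n_pdmr:
            picked = rng.choice(len(gene_names), size=config.n_pdmr, replace=False)
            for i in np.sort(picked):
                b = float(np.clip(base_means.iloc[i], 0.15, 0.60))
                base_means.iloc[i] = b  # keep headroom for the planted shift
                direction = rng.choice(["hyper", "hypo"])
                shift = config.pdmr_delta if direction == "hyper" else -config.pdmr_delta
                wgbs_mean = float(np.clip(b + shift, 0.02, 0.98))
                pdmr_rows.append((gene_names[i], b, wgbs_mean, b, wgbs_mean - b, direction))
    pdmr = pd.DataFrame(
        pdmr_rows, columns=["gene", "base_mean", "wgbs_mean", "array_mean", "delta", "direction"]
    )
    return TruthSet(canyons, dmp_sites, pdmr, base_means)


def _mu_map(annotation: Annotation, truth: TruthSet, config: SimulationConfig,
            group: str, cohort: str = "wgbs") -> dict:
    """Per-chromosome local mean methylation at every CpG for one group.

    Layering order: background -> islands -> promoter base means ->
    planted promoter effects -> DMP sites -> canyons (with border ramp).
    """
    tumor = group in config.tumor_groups or cohort == "array"
    bg = config.background_meth + (config.tumor_background_delta if tumor else 0.0)
    isl_mu = config.island_meth + (config.tumor_island_delta if tumor else 0.0)
    bg = float(np.clip(bg, _EPS, 1 - _EPS))
    isl_mu = float(np.clip(isl_mu, _EPS, 1 - _EPS))
    out = {}
    promoters = annotation.promoters if truth.promoter_base_means is not None else None
    for chrom, pos in annotation.cpg_positions.items():
        mu = np.full(len(pos), bg)
        isl = annotation.islands[annotation.islands["chrom"] == chrom]
        for row in isl.itertuples(index=False):
            lo, hi = np.searchsorted(pos, [row.start, row.end])
            mu[lo:hi] = isl_mu
        if promoters is not None:
            sub = promoters[promoters["chrom"] == chrom]
            planted = truth.pdmr_promoters.set_index("gene") if len(truth.pdmr_promoters) else None
            for row in sub.itertuples():
                lo, hi = np.searchsorted(pos, [row.start, row.end])
                m = truth.promoter_base_means.get(row.name, None)
                if planted is not None and row.name in planted.index:
                    m = (
                        planted.loc[row.name, "wgbs_mean"]
                        if cohort == "wgbs"
                        else planted.loc[row.name, "array_mean"]
                    )
                if m is not None:
                    mu[lo:hi] = m
        if len(truth.dmp_sites):
            sub = truth.dmp_sites[truth.dmp_sites["chrom"] == chrom]
            for row in sub.itertuples(index=False):
                i = np.searchsorted(pos, row.pos)
                if i < len(pos) and pos[i] == row.pos:
                    mu[i] = row.mu_tumor if tumor else row.mu_normal
        sub = truth.canyons[truth.canyons["chrom"] == chrom]
        for row in sub.itertuples(index=False):
            if group not in row.groups and cohort == "wgbs":
                continue
            lo, hi = np.searchsorted(pos, [row.start, row.end])
            if hi <= lo:
                continue
            p = pos[lo:hi]
            edge = np.minimum(p - row.start, (row.end - 1) - p).astype(float)
            ramp = np.clip(edge / max(config.canyon_ramp_bp, 1), 0.0, 1.0)
            local = mu[lo:hi]
            mu[lo:hi] = config.canyon_meth * ramp + local * (1.0 - ramp)
        out[chrom] = np.clip(mu, _EPS, 1 - _EPS)
    return out


def simulate_sample(
    annotation: Annotation,
    truth: TruthSet,
    group_label: str,
    seed,
    config: SimulationConfig,
) -> pd.DataFrame:
    """One WGBS sample: negative-binomial coverage and beta-binomial
    methylated counts at every CpG.  Zero-coverage sites are emitted with
    meth_count 0 and undefined ratio."""
    rng = np.random.default_rng(seed)
    mu_map = _mu_map(annotation, truth, config, group_label, cohort="wgbs")
    parts = []
    r = 1.0 / config.coverage_dispersion
    p_nb = r / (r + config.mean_coverage)
    for chrom, pos in annotation.cpg_positions.items():
        mu = mu_map[chrom]
        cov = rng.negative_binomial(r, p_nb, size=len(pos))
        if np.isinf(config.bb_precision):
            meth = np.rint(cov * mu).astype(np.int64)
        else:
            a = mu * config.bb_precision
            b = (1.0 - mu) * config.bb_precision
            p_site = rng.beta(a, b)
            meth = rng.binomial(cov, p_site)
        parts.append(records_from_arrays(chrom, pos, cov, meth))
    return pd.concat(parts, ignore_index=True)


def batch_distort(beta: np.ndarray, compression: float) -> np.ndarray:
    """Monotone logistic compression of beta values toward 0.5.

    ``compression`` > 1 shrinks the logit scale by that factor; 1.0 is the
    identity (returned unchanged, bit-exact).
    """
    if compression == 1.0:
        return beta
    x = np.clip(beta, _EPS, 1 - _EPS)
    return expit(logit(x) / compression)


def simulate_array_cohort(
    annotation: Annotation, truth: TruthSet, config: SimulationConfig, seeds
) -> pd.DataFrame:
    """Array-like cohort: beta values at probe positions only, Beta noise
    around the array-side planted means, then the configured batch
    distortion.  Returns a (chrom, pos)-indexed probe x sample frame."""
    mu_map = _mu_map(annotation, truth, config, config.array_group, cohort="array")
    probe_mu = []
    index = []
    for chrom, sub in config_probes_by_chrom(annotation):
        pos_all = annotation.cpg_positions[chrom]
        idx = np.searchsorted(pos_all, sub)
        probe_mu.append(mu_map[chrom][idx])
        index += [(chrom, int(p)) for p in sub]
    mu = np.concatenate(probe_mu) if probe_mu else np.empty(0)
    cols = {}
    for j, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        a = mu * config.array_precision
        b = (1.0 - mu) * config.array_precision
        beta = rng.beta(a, b)
        cols[f"{config.array_group}_{j+1:02d}"] = batch_distort(beta, config.batch_shift)
    return pd.DataFrame(cols, index=pd.MultiIndex.from_tuples(index, names=["chrom", "pos"]))


def config_probes_by_chrom(annotation: Annotation):
    for chrom, sub in annotation.probes.groupby("chrom", sort=False):
        yield chrom, np.sort(sub["pos"].to_numpy())


def simulate_cohorts(config: SimulationConfig):
    """Generate the full study: WGBS samples per group, the array-like
    cohort (if configured), and the truth set.

    Returns ``(wgbs_samples_by_group, array_matrix_or_None, truth)`` where
    ``wgbs_samples_by_group`` maps group -> {sample id -> methylome frame}.
    """
    config.validate()
    for g, n in config.group_sizes.items():
        if n < 2:
            raise ValueError(f"group {g!r} has < 2 samples; rank tests undefined")
    if config.array_size and config.array_size < 2:
        raise ValueError("array cohort needs >= 2 samples")
    root = np.random.SeedSequence(config.seed)
    ss_annot, ss_truth, ss_samples, ss_array = root.spawn(4)
    annotation = simulate_annotation(config, np.random.default_rng(ss_annot))
    truth = plant_truth(config, annotation, np.random.default_rng(ss_truth))
    wgbs = {}
    n_total = sum(config.group_sizes.values())
    child = iter(ss_samples.spawn(n_total))
    for group, n in config.group_sizes.items():
        wgbs[group] = {}
        for i in range(n):
            sid = f"{group}_{i+1:02d}"
            wgbs[group][sid] = simulate_sample(annotation, truth, group, next(child), config)
    array_matrix = None
    if config.array_size:
        array_matrix = simulate_array_cohort(
            annotation, truth, config, ss_array.spawn(config.array_size)
        )
    return wgbs, array_matrix, truth, annotation


def match_canyons(
    truth_canyons: pd.DataFrame,
    called: pd.DataFrame,
    group: str | None = None,
    max_boundary_err: int = 500,
):
    """Score called canyons against the planted truth.

    A planted canyon is recovered when a called interval overlaps it with
    both boundary errors <= ``max_boundary_err`` bp.  Called intervals
    overlapping no planted canyon are false calls.  Returns
    (recovered_flags, boundary_errors, n_false).
    """
    tr = truth_canyons
    if group is not None:
        tr = tr[[group in g for g in tr["groups"]]]
    recovered = []
    errors = []
    used = np.zeros(len(called), dtype=bool)
    for row in tr.itertuples(index=False):
        best = None
        for i, c in enumerate(called.itertuples(index=False)):
            if c.chrom != row.chrom or c.start >= row.end or row.start >= c.end:
                continue
            err = max(abs(c.start - row.start), abs(c.end - row.end))
            if best is None or err < best[1]:
                best = (i, err)
        if best is not None:
            used[best[0]] = True
            errors.append(best[1])
            recovered.append(best[1] <= max_boundary_err)
        else:
            errors.append(np.inf)
            recovered.append(False)
    overlapping_any = np.zeros(len(called), dtype=bool)
    for i, c in enumerate(called.itertuples(index=False)):
        for row in tr.itertuples(index=False):
            if c.chrom == row.chrom and c.start < row.end and row.start < c.end:
                overlapping_any[i] = True
                break
    n_false = int((~overlapping_any).sum())
    return np.array(recovered, dtype=bool), np.array(errors), n_false


def simulate_promoter_matrix(
    n_promoters: int,
    group_sizes: dict,
    seed,
    precision: float = 30.0,
    planted: pd.DataFrame | None = None,
):
    """Promoter x sample beta-value matrix with Beta noise around shared
    per-promoter means; ``planted`` (gene, group, mean) rows override the
    mean for specific promoter/group pairs.  Fast path for error-control
    simulations on pre-aggregated promoter means."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_promoters)]
    base = rng.uniform(0.1, 0.9, n_promoters)
    cols = {}
    groups = {}
    for group, n in group_sizes.items():
        mu = base.copy()
        if planted is not None:
            for row in planted.itertuples(index=False):
                if row.group == group:
                    mu[genes.index(row.gene)] = row.mean
        for i in range(n):
            sid = f"{group}_{i+1:02d}"
            mu_c = np.clip(mu, _EPS, 1 - _EPS)
            cols[sid] = rng.beta(mu_c * precision, (1 - mu_c) * precision)
            groups[sid] = group
    values = pd.DataFrame(cols, index=genes)
    features = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n_promoters) * 10_000,
         "end": np.arange(n_promoters) * 10_000 + 1_500},
        index=genes,
    )
    from .io import MethylationMatrix

    return MethylationMatrix(values, features, pd.Series(groups))


def simulate_expression(
    meth_matrix: pd.DataFrame, seed, slope: float = 2.0, noise_sd: float = 0.5,
    intercept: float = 5.0,
) -> pd.DataFrame:
    """Repression-model expression: expr = intercept - slope * meth + noise."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, meth_matrix.shape)
    return intercept - slope * meth_matrix + noise


def config_to_flat(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["group_sizes"] = ";".join(f"{k}={v}" for k, v in config.group_sizes.items())
    d["canyon_groups"] = (
        "" if config.canyon_groups is None
        else "|".join(",".join(g) for g in config.canyon_groups)
    )
    return d
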