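"""Ground-truth simulators for every input the pipeline consumes.

The generators emulate the statistical structure of a whole-life-cycle
RNA-seq study of C. elegans:

* bulk embryo time series in which each sample is a population of
  embryos with a drifting mean age and growing age variance (so each
  observed expression vector is a stage mixture);
* stage-specific expression programs with maternal / zygotic /
  piecewise-linear archetypes on a uniform 30-min stage grid;
* splice-junction pairs sharing a donor site whose minor-form fraction
  follows designed trajectories crossing the 0.85 / 0.15 usage
  thresholds;
* a small annotated genome with operons (a subset carrying internal
  promoters: elevated SL1 at the second gene and a longer gene1->gene2
  gap), interspersed single genes, noncoding genes, low-level intergenic
  background transcription optionally coupled to local coding
  expression, and near-identical histone gene clusters;
* reads drawn from histone gene families with known copy proportions.

All randomness flows from a single seed through named substreams, so
each component is individually reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stages import composition_matrix, stage_grid

__all__ = [
    "SeriesSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_series",
    "simulate_stage_expression",
    "simulate_junctions",
    "simulate_genome",
    "simulate_changepoint_series",
    "simulate_family_reads",
]


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator derived from (seed, name)."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class SeriesSpec:
    """Staging parameters of one experimental embryo time series.

    t0            initial mean standard developmental time (minutes)
    growth_rate   population growth rate relative to the standard clock
    sigma0        initial SD of the stage distribution (minutes)
    variance_rate increase of the stage-distribution variance per minute
                  of experiment time (minutes^2 / minute)
    sample_times  collection times (minutes into the experiment)
    """

    t0: float
    growth_rate: float
    sigma0: float
    variance_rate: float
    sample_times: tuple[float, ...]

    def __post_init__(self):
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if self.sigma0 < 0 or self.variance_rate < 0:
            raise ValueError("sigma0 and variance_rate must be nonnegative")

    def age_mean(self, t: float) -> float:
        return self.t0 + self.growth_rate * t

    def age_var(self, t: float) -> float:
        return self.sigma0**2 + self.variance_rate * t


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the expression-series simulator."""

    n_genes: int = 200
    n_stages: int = 20
    stage_step: float = 30.0
    series_specs: tuple[SeriesSpec, ...] = ()
    lognormal_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if self.lognormal_sd < 0:
            raise ValueError("lognormal_sd must be nonnegative")

    @property
    def stage_times(self) -> np.ndarray:
        return stage_grid(self.n_stages, self.stage_step)


def default_series_specs(n_stages: int = 20, stage_step: float = 30.0) -> tuple[SeriesSpec, ...]:
    """Three replicate series spanning the stage grid.

    Growth rates 0.9 / 1.0 / 1.15 and mild start/variance differences
    mimic replicate embryo preparations growing at slightly different
    speeds; 12 samples per series at 45-min spacing cover the grid.
    """
    span = stage_step * (n_stages - 1)
    times = tuple(np.linspace(0.0, span, 12))
    return (
        SeriesSpec(t0=20.0, growth_rate=0.9, sigma0=15.0, variance_rate=0.5, sample_times=times),
        SeriesSpec(t0=0.0, growth_rate=1.0, sigma0=12.0, variance_rate=0.4, sample_times=times),
        SeriesSpec(t0=10.0, growth_rate=1.15, sigma0=18.0, variance_rate=0.6, sample_times=times),
    )


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must recover."""

    stage_expression: pd.DataFrame | None = None
    per_sample_composition: dict[str, pd.DataFrame] = field(default_factory=dict)
    changepoints_per_gene: dict[str, tuple[int, list[float], list[float]]] = field(
        default_factory=dict
    )
    archetype_per_gene: dict[str, str] = field(default_factory=dict)
    junction_truth: pd.DataFrame | None = None
    operon_truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# stage-specific expression programs
# ---------------------------------------------------------------------------

def _piecewise_linear(t: np.ndarray, intercept: float, knots: list[float], slopes: list[float]):
    """Continuous piecewise-linear curve: slopes[j] applies after knots[j-1]."""
    y = intercept + slopes[0] * t
    for tau, ds in zip(knots, np.diff(slopes)):
        y = y + ds * np.clip(t - tau, 0.0, None)
    return y


def simulate_stage_expression(
    n_genes: int, stage_times: np.ndarray, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict, dict]:
    """Gene-by-stage dcpm programs built from piecewise-linear log profiles.

    Archetype mix (fractions chosen to resemble an embryonic
    transcriptome): 25% maternal (high at the first stage, decaying),
    30% zygotic (rising to a mid/late peak, then falling), 15% flat, and
    30% generic piecewise-linear with 0-3 change points.  Amplitudes are
    lognormal so dcpm spans several orders of magnitude.

    Returns (matrix, changepoints_per_gene, archetype_per_gene); the
    change-point truth is (count, knot times, per-segment slopes) of the
    log1p(dcpm) profile.
    """
    span = stage_times[-1] - stage_times[0]
    interior = stage_times[1:-1]
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    mat = np.zeros((n_genes, stage_times.size))
    cps: dict[str, tuple[int, list[float], list[float]]] = {}
    arch: dict[str, str] = {}
    kinds = rng.choice(
        ["maternal", "zygotic", "flat", "generic"], size=n_genes, p=[0.25, 0.30, 0.15, 0.30]
    )
    for i, gid in enumerate(gene_ids):
        amp = float(np.exp(rng.normal(0.5, 1.3)))  # peak dcpm, median ~1.6
        a = np.log1p(amp)
        kind = kinds[i]
        if kind == "maternal":
            tau = float(rng.choice(interior))
            fast = -a / max(tau, 1.0) * rng.uniform(0.8, 1.2)
            slow = fast * rng.uniform(0.0, 0.2)
            knots, slopes, intercept = [tau], [fast, slow], a
        elif kind == "zygotic":
            lo, hi = interior[interior > span * 0.2], None
            tau1 = float(rng.choice(lo))
            up = a / tau1 * rng.uniform(0.9, 1.1)
            later = interior[interior > tau1]
            if later.size and rng.random() < 0.8:
                tau2 = float(rng.choice(later))
                down = -up * rng.uniform(0.3, 1.0)
                knots, slopes = [tau1, tau2], [up, 0.0, down]
            else:
                knots, slopes = [tau1], [up, 0.0]
            intercept = a * rng.uniform(0.0, 0.1)
        elif kind == "flat":
            knots, slopes, intercept = [], [rng.normal(0.0, 0.05 * a / span)], a
        else:
            k = int(rng.integers(0, 4))
            knots = sorted(rng.choice(interior, size=k, replace=False).tolist()) if k else []
            smax = 2.0 * a / span
            slopes = rng.uniform(-smax, smax, size=k + 1).tolist()
            intercept = a * rng.uniform(0.2, 1.0)
        logp = _piecewise_linear(stage_times, intercept, knots, slopes)
        logp = np.clip(logp, 0.0, None)
        mat[i] = np.expm1(logp)
        cps[gid] = (len(knots), [float(x) for x in knots], [float(s) for s in slopes])
        arch[gid] = kind
    df = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                      columns=[f"stage{k:02d}" for k in range(stage_times.size)])
    return df, cps, arch


def simulate_series(config: SimulationConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Simulate observed expression matrices for each series.

    For series ``s`` and sample time ``t``, the embryo-age distribution
    is Gaussian with mean ``t0 + growth_rate*t`` and variance
    ``sigma0^2 + variance_rate*t``, discretized onto the stage grid; the
    observed dcpm vector is the composition-weighted mixture of the
    stage program with multiplicative lognormal noise.
    """
    specs = config.series_specs or default_series_specs(config.n_stages, config.stage_step)
    stage_times = config.stage_times
    rng_expr = _rng(config.seed, "stage_expression")
    expr, cps, arch = simulate_stage_expression(config.n_genes, stage_times, rng_expr)
    truth = GroundTruth(stage_expression=expr, changepoints_per_gene=cps, archetype_per_gene=arch)

    series: dict[str, pd.DataFrame] = {}
    rng_noise = _rng(config.seed, "observation_noise")
    for si, spec in enumerate(specs):
        sid = f"series{si}"
        times = np.asarray(spec.sample_times, dtype=float)
        means = spec.t0 + spec.growth_rate * times
        variances = spec.sigma0**2 + spec.variance_rate * times
        W = composition_matrix(means, variances, stage_times)
        sample_ids = [f"{sid}_s{j:02d}" for j in range(times.size)]
        truth.per_sample_composition[sid] = pd.DataFrame(
            W, index=pd.Index(sample_ids, name="sample_id"), columns=expr.columns
        )
        X = expr.to_numpy() @ W.T
        if config.lognormal_sd > 0:
            X = X * np.exp(rng_noise.normal(0.0, config.lognormal_sd, size=X.shape))
        df = pd.DataFrame(X, index=expr.index, columns=sample_ids)
        df.attrs["sample_times"] = dict(zip(sample_ids, times))
        series[sid] = df
    return series, truth


def simulate_changepoint_series(
    n_genes: int,
    time_grid: np.ndarray,
    noise_sd: float = 0.15,
    min_slope_sds: float = 3.0,
    max_k: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, tuple[int, list[float], list[float]]]]:
    """Benchmark series for change-point recovery.

    Each gene is a continuous piecewise-linear curve over ``time_grid``
    with K ~ uniform{0..max_k} knots at interior grid points (knots at
    least three grid steps apart, so every segment holds enough points
    to witness its slope) plus iid Gaussian noise.  Slope changes
    at knots are sized to displace the curve by at least
    ``min_slope_sds`` noise SDs per grid step, so each kink is
    detectable against the noise.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(time_grid, dtype=float)
    step = float(np.median(np.diff(t)))
    truth: dict[str, tuple[int, list[float], list[float]]] = {}
    mat = np.zeros((n_genes, t.size))
    gene_ids = [f"cp{i:04d}" for i in range(n_genes)]
    interior = t[2:-2]
    for i, gid in enumerate(gene_ids):
        k = int(rng.integers(0, max_k + 1))
        knots: list[float] = []
        attempts = 0
        while len(knots) < k and attempts < 100:
            cand = float(rng.choice(interior))
            if all(abs(cand - x) >= 3 * step for x in knots):
                knots.append(cand)
            attempts += 1
        knots = sorted(knots)
        k = len(knots)
        unit = min_slope_sds * noise_sd / step  # slope giving min_slope_sds SDs per grid step
        slopes = [rng.uniform(-1.0, 1.0) * unit]
        for _ in range(k):
            delta_mag = rng.uniform(1.0, 2.0) * unit
            sign = rng.choice([-1.0, 1.0])
            slopes.append(slopes[-1] + sign * delta_mag)
        y = _piecewise_linear(t, rng.uniform(0.0, 3.0), knots, slopes)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=t.size)
        mat[i] = y
        truth[gid] = (k, knots, [float(s) for s in slopes])
    df = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                      columns=[f"t{int(x):04d}" for x in t])
    df.attrs["time_grid"] = t
    return df, truth


# ---------------------------------------------------------------------------
# splice junctions
# ---------------------------------------------------------------------------

_TRAJECTORIES = ("constant_low", "maternal_minor", "late_minor", "mid_minor", "balanced")


def _minor_fraction(kind: str, frac: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Designed minor-form fraction over normalized sample positions in [0,1]."""
    if kind == "constant_low":
        return np.full_like(frac, rng.uniform(0.01, 0.08))
    if kind == "maternal_minor":  # minor form predominates early, then vanishes
        return np.where(frac < rng.uniform(0.25, 0.45), rng.uniform(0.88, 0.97), rng.uniform(0.02, 0.10))
    if kind == "late_minor":
        return np.where(frac > rng.uniform(0.55, 0.75), rng.uniform(0.88, 0.97), rng.uniform(0.02, 0.10))
    if kind == "mid_minor":
        lo, hi = sorted(rng.uniform(0.2, 0.8, size=2))
        inside = (frac >= lo) & (frac <= min(hi, lo + 0.4) + 0.2)
        return np.where(inside, rng.uniform(0.88, 0.97), rng.uniform(0.02, 0.10))
    return np.full_like(frac, rng.uniform(0.3, 0.5))  # balanced


def simulate_junctions(
    n_pairs: int = 60,
    n_constitutive: int = 40,
    n_samples: int = 24,
    mean_depth: float = 120.0,
    novel_minor_frac: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Splice-junction count table with designed alternative-usage pairs.

    Each pair shares a donor site inside one gene; the minor junction's
    designed usage trajectory is one of five shapes (constant-low,
    maternal-minor, late-minor, mid-minor, balanced), three of which
    cross the 0.85/0.15 thresholds by design.  Spanning-read counts are
    Poisson around the designed expectations.  Constitutive junctions
    and a handful of intergenic junctions are added as background.

    Returns (table, truth): ``table`` has one row per junction with
    per-sample count columns; ``truth`` records the designed trajectory
    per pair.
    """
    rng = np.random.default_rng(seed)
    frac = np.arange(n_samples) / max(n_samples - 1, 1)
    samples = [f"s{j:02d}" for j in range(n_samples)]
    rows, truth_rows = [], []
    pos = 1000
    for p in range(n_pairs):
        kind = _TRAJECTORIES[p % len(_TRAJECTORIES)]
        rho = _minor_fraction(kind, frac, rng)
        depth = rng.gamma(4.0, mean_depth / 4.0, size=n_samples)
        minor_counts = rng.poisson(depth * rho)
        major_counts = rng.poisson(depth * (1.0 - rho))
        gene = f"jg{p:04d}"
        donor = pos
        major_end, minor_end = pos + 200, pos + 200 + int(rng.integers(60, 400))
        minor_status = "novel" if rng.random() < novel_minor_frac else "known"
        rows.append(["chrJ", donor, major_end, "+", gene, "known", *major_counts])
        rows.append(["chrJ", donor, minor_end, "+", gene, minor_status, *minor_counts])
        truth_rows.append(
            {
                "pair_id": f"pair{p:04d}",
                "gene_id": gene,
                "kind": kind,
                "major": f"chrJ:{donor}-{major_end}:+",
                "minor": f"chrJ:{donor}-{minor_end}:+",
                "rho_design": ",".join(f"{r:.4f}" for r in rho),
            }
        )
        pos += 5000
    for c in range(n_constitutive):
        depth = rng.gamma(4.0, mean_depth / 4.0, size=n_samples)
        counts = rng.poisson(depth)
        gene = f"cg{c:04d}" if c % 5 else ""  # every 5th is intergenic
        rows.append(["chrJ", pos, pos + int(rng.integers(50, 300)), "+", gene,
                     "known" if gene else "novel", *counts])
        pos += 3000
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id", "status", *samples])
    table.insert(0, "junction_id", [
        f"{r.chrom}:{r.start}-{r.end}:{r.strand}" for r in table.itertuples()
    ])
    return table, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# genome, operons, SL counts, chromatin, histones, background transcription
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeConfig:
    """Layout of the synthetic annotated genome."""

    n_operons: int = 120
    genes_per_operon: int = 2
    n_singletons: int = 60
    n_noncoding: int = 40
    n_samples: int = 12
    gene_len: int = 1500
    operon_gap: int = 120          # gene1->gene2 gap without internal promoter
    internal_extra_gap: int = 700  # additional gap when an internal promoter exists
    internal_promoter_frac: float = 0.12
    intergenic_gap_mean: float = 2500.0
    background_coupling: float = 0.5   # intergenic rate per unit of local coding dcpm
    background_base: float = 0.004     # baseline intergenic dcpm
    histone_clusters: int = 2
    copies_per_cluster: int = 4
    histone_len: int = 400
    discriminating_bases: int = 5
    n_chromosomes: int = 2
    seed: int = 0


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def simulate_genome(config: GenomeConfig) -> dict:
    """Annotated genome + coverage + SL counts + chromatin + histone families.

    Layout: operons and single genes alternate along ``n_chromosomes``
    chromosomes separated by exponential intergenic gaps.  A fraction of
    operons carry an internal promoter at their second gene: its SL1
    expression is boosted (SL2 retained) and the gene1->gene2 gap grows
    by ``internal_extra_gap``.  Intergenic background coverage in each
    gap is ``background_base + background_coupling * local coding dcpm``
    with multiplicative noise; setting the coupling to zero makes
    intergenic signal independent of coding expression.  The chromatin
    track places a Gaussian peak at every promoter (first genes, single
    genes, and internally promoted second genes).

    Returns a dict with keys: annotation (feature DataFrame), chrom_sizes,
    genome (chrom -> sequence), coverage (sample -> bedGraph DataFrame),
    expression (gene x sample dcpm), sl1/sl2 (gene x sample dcpm),
    chromatin (bedGraph DataFrame), histone_families, operon_truth,
    total_mapped_reads.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"s{j:02d}" for j in range(config.n_samples)]
    phase = np.linspace(0.0, 1.0, config.n_samples)

    features = []
    gene_rows = []          # (gene_id, chrom, start, end, strand, kind, operon, position)
    operon_truth_rows = []
    chrom_cursor: dict[str, int] = {}
    chroms = [f"chr{i+1}" for i in range(config.n_chromosomes)]
    for c in chroms:
        chrom_cursor[c] = 500

    def _next_chrom(i):
        return chroms[i % len(chroms)]

    n_units = config.n_operons + config.n_singletons + config.n_noncoding
    unit_kinds = (["operon"] * config.n_operons + ["singleton"] * config.n_singletons
                  + ["noncoding"] * config.n_noncoding)
    rng.shuffle(unit_kinds)

    op_i = sg_i = nc_i = 0
    for u in range(n_units):
        chrom = _next_chrom(u)
        cur = chrom_cursor[chrom] + int(rng.exponential(config.intergenic_gap_mean)) + 200
        kind = unit_kinds[u]
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "operon":
            oid = f"op{op_i:04d}"
            internal = rng.random() < config.internal_promoter_frac
            gap = config.operon_gap + (config.internal_extra_gap if internal else 0)
            gstarts = []
            s = cur
            for gpos in range(config.genes_per_operon):
                gid = f"{oid}_g{gpos+1}"
                gene_rows.append((gid, chrom, s, s + config.gene_len, strand, "coding", oid, gpos + 1))
                gstarts.append(s)
                s += config.gene_len + gap
            features.append(
                dict(seqid=chrom, source="sim", featuretype="operon", start=cur,
                     end=s - gap, score=".", strand=strand, frame=".",
                     attributes={"ID": oid, "internal_promoter": str(int(internal))})
            )
            operon_truth_rows.append(
                {"operon_id": oid, "internal_promoter": bool(internal),
                 "intergenic_distance": gap, "gene1": f"{oid}_g1", "gene2": f"{oid}_g2"}
            )
            chrom_cursor[chrom] = s
            op_i += 1
        elif kind == "singleton":
            gid = f"sg{sg_i:04d}"
            gene_rows.append((gid, chrom, cur, cur + config.gene_len, strand, "coding", "", 0))
            chrom_cursor[chrom] = cur + config.gene_len
            sg_i += 1
        else:
            gid = f"nc{nc_i:04d}"
            glen = config.gene_len // 3
            gene_rows.append((gid, chrom, cur, cur + glen, strand, "noncoding", "", 0))
            chrom_cursor[chrom] = cur + glen
            nc_i += 1

    # histone clusters of near-identical copies, placed after the genes
    histone_families: dict[str, dict[str, str]] = {}
    for h in range(config.histone_clusters):
        chrom = _next_chrom(h)
        base = _random_seq(rng, config.histone_len)
        fam = f"hcl{h}"
        members = {}
        disc = rng.choice(config.histone_len, size=config.discriminating_bases, replace=False)
        for m in range(config.copies_per_cluster):
            seq = list(base)
            for pcol in disc:
                # each copy gets its own base at a subset of discriminating sites
                if rng.random() < 0.7:
                    seq[pcol] = rng.choice(list("ACGT"))
            members[f"{fam}_his{m}"] = "".join(seq)
        histone_families[fam] = members
        cur = chrom_cursor[chrom] + 1000
        for m, (mid, _) in enumerate(members.items()):
            s = cur + m * (config.histone_len + 200)
            gene_rows.append((mid, chrom, s, s + config.histone_len, "+", "histone", fam, m))
        chrom_cursor[chrom] = cur + config.copies_per_cluster * (config.histone_len + 200)

    chrom_sizes = {c: chrom_cursor[c] + 2000 for c in chroms}
    genome = {c: _random_seq(rng, n) for c, n in chrom_sizes.items()}

    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "kind", "group", "position"],
    )
    for row in genes.itertuples(index=False):
        ftype = {"coding": "gene", "noncoding": "ncRNA_gene", "histone": "gene"}[row.kind]
        attrs = {"ID": row.gene_id, "biotype": row.kind}
        if row.group:
            attrs["group"] = row.group
            attrs["position"] = str(row.position)
        features.append(
            dict(seqid=row.chrom, source="sim", featuretype=ftype, start=row.start,
                 end=row.end, score=".", strand=row.strand, frame=".", attributes=attrs)
        )
    annotation = pd.DataFrame(features)

    # per-gene expression over samples (dcpm): lognormal level x smooth stage
    # modulation.  Operon second genes are driven by read-through from the
    # first gene (so their expression tracks gene 1); internal promoters add
    # an independent component, which both boosts SL1 and decorrelates the
    # pair's expression.
    n_genes = len(genes)
    level = np.exp(rng.normal(0.3, 1.0, size=n_genes))
    mod_phase = rng.uniform(0, 1, size=n_genes)
    mod = 0.5 + 0.5 * np.cos(2 * np.pi * (phase[None, :] - mod_phase[:, None]))
    expr = level[:, None] * (0.3 + 0.7 * mod)
    expr *= np.exp(rng.normal(0, 0.15, size=expr.shape))

    sl1 = np.zeros_like(expr)
    sl2 = np.zeros_like(expr)
    internal_by_operon = {r["operon_id"]: r["internal_promoter"] for r in operon_truth_rows}
    gene_pos = {g: i for i, g in enumerate(genes.gene_id)}
    for i, row in enumerate(genes.itertuples(index=False)):
        if row.kind != "coding":
            continue
        if row.group and row.position >= 2:
            first_idx = gene_pos[f"{row.group}_g1"]
            readthrough = expr[first_idx] * rng.uniform(0.5, 0.9)
            readthrough = readthrough * np.exp(rng.normal(0, 0.1, size=readthrough.size))
            own = expr[i] * 0.02  # basal leak from cryptic initiation
            if internal_by_operon.get(row.group, False):
                own = own + expr[i] * rng.uniform(0.8, 1.5)
            expr[i] = readthrough + own
            capture = rng.uniform(0.6, 0.9)
            sl2[i] = readthrough * capture
            sl1[i] = own * capture
        else:
            sl1[i] = expr[i] * rng.uniform(0.6, 0.95)
            sl2[i] = expr[i] * rng.uniform(0.0, 0.03)
    expression = pd.DataFrame(expr, index=pd.Index(genes.gene_id, name="gene_id"), columns=samples)
    sl1 = pd.DataFrame(sl1, index=expression.index, columns=samples)
    sl2 = pd.DataFrame(sl2, index=expression.index, columns=samples)

    # coverage tracks: per-gene body coverage + intergenic background in gaps
    coding = genes[genes.kind != "noncoding"]
    coverage: dict[str, pd.DataFrame] = {}
    bg_truth = []
    for j, sample in enumerate(samples):
        ivals = []
        for i, row in enumerate(genes.itertuples(index=False)):
            ivals.append((row.chrom, row.start, row.end, expr[i, j]))
        for c in chroms:
            sub = genes[genes.chrom == c].sort_values("start")
            bounds = list(zip(sub.end.iloc[:-1], sub.start.iloc[1:]))
            local = 0.5 * (expr[sub.index[:-1], j] + expr[sub.index[1:], j])
            for (gap_s, gap_e), loc in zip(bounds, local):
                if gap_e - gap_s < 50:
                    continue
                rate = config.background_base + config.background_coupling * 0.01 * loc
                rate *= float(np.exp(rng.normal(0, 0.5)))
                ivals.append((c, int(gap_s) + 10, int(gap_e) - 10, rate))
                if j == 0:
                    bg_truth.append({"chrom": c, "start": int(gap_s) + 10,
                                     "end": int(gap_e) - 10, "coupled": config.background_coupling > 0})
        cov = pd.DataFrame(ivals, columns=["chrom", "start", "end", "value"])
        coverage[sample] = cov.sort_values(["chrom", "start"]).reset_index(drop=True)

    # chromatin signal: peak at every promoter-bearing TSS
    chrom_rows = []
    for row in genes.itertuples(index=False):
        if row.kind != "coding":
            continue
        promoted = (row.position <= 1) or internal_by_operon.get(row.group, False)
        if not promoted:
            continue
        tss = row.start if row.strand == "+" else row.end - 1
        for off in range(-300, 301, 50):
            center = tss + off
            val = 5.0 * np.exp(-(off**2) / (2 * 120.0**2))
            chrom_rows.append((row.chrom, max(center - 25, 0), center + 25, val))
    chromatin = (
        pd.DataFrame(chrom_rows, columns=["chrom", "start", "end", "value"])
        .sort_values(["chrom", "start"]).reset_index(drop=True)
    )

    return {
        "annotation": annotation,
        "genes": genes,
        "chrom_sizes": chrom_sizes,
        "genome": genome,
        "coverage": coverage,
        "expression": expression,
        "sl1": sl1,
        "sl2": sl2,
        "chromatin": chromatin,
        "histone_families": histone_families,
        "operon_truth": pd.DataFrame(operon_truth_rows),
        "background_truth": pd.DataFrame(bg_truth),
        "total_mapped_reads": 1_000_000,
        "samples": samples,
    }


def simulate_family_reads(
    family: dict[str, str],
    proportions: dict[str, float],
    n_reads: int,
    read_length: int = 50,
    error_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Reads drawn from histone family members at known copy proportions.

    Each read is an exact (or error-perturbed) substring of its source
    member at a uniform start position.  Returns a DataFrame with
    read_id, source (truth), position, sequence.
    """
    rng = np.random.default_rng(seed)
    members = list(family)
    p = np.array([proportions[m] for m in members], dtype=float)
    p = p / p.sum()
    length = len(next(iter(family.values())))
    if any(len(s) != length for s in family.values()):
        raise ValueError("family members must be length-matched (no-indel model)")
    src = rng.choice(len(members), size=n_reads, p=p)
    starts = rng.integers(0, length - read_length + 1, size=n_reads)
    rows = []
    for i in range(n_reads):
        m = members[src[i]]
        s = int(starts[i])
        seq = family[m][s : s + read_length]
        if error_rate > 0:
            seq = "".join(
                rng.choice(list("ACGT")) if rng.random() < error_rate else b for b in seq
            )
        rows.append((f"r{i:06d}", m, s, seq))
    return pd.DataFrame(rows, columns=["read_id", "source", "position", "sequence"])
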