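"""Synthetic islet Ca2+ cohorts, proteomes, and genomic fixtures.

The generator is phenomenological, not mechanistic: it emulates the
statistical structure the downstream analysis assumes, so that every stage
is testable without the original imaging/proteomic/genomic downloads.

Archetypes mirror the strain-level phenotype classes seen across
genetically diverse mouse panels:

* ``slow``    -- square-like bursts, period 2-10 min (classical strains);
* ``fast``    -- square-like bursts, period < 2 min (wild-derived strains);
* ``plateau`` -- sustained elevation at baseline + amplitude;
* ``silent``  -- flat at baseline (diabetic/basal responses);
* ``mixed``   -- a slow burst train with a smaller, always-on fast train
  superimposed (2:1 amplitude ratio), the NOD-like phenotype.

Bursts are synthesized as logistic-edged square waves so the programmed
duty cycle and the 50%-threshold active duration coincide.  Default
acquisition matches the study protocol: 6-s sampling (0.1 min) over four
40-min condition segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .traceio import SegmentSchedule, Trace

__all__ = [
    "WaveSpec",
    "CohortSpec",
    "PlantSpec",
    "make_trace",
    "make_cohort",
    "make_protein_matrix",
    "make_genomic_fixtures",
    "make_nomination_demo",
    "make_planted_cohort_params",
    "GLYCEMIC_TRAITS",
]

_ARCHETYPES = ("slow", "fast", "plateau", "silent", "mixed")

#: Controlled glycemic-trait vocabulary used for synthetic SNP records.
GLYCEMIC_TRAITS = (
    "fasting_insulin",
    "fasting_glucose",
    "HbA1c",
    "T2D",
    "2hr_glucose",
    "HOMA-B",
)


@dataclass(frozen=True)
class WaveSpec:
    """One archetype's waveform parameters for a single condition segment."""

    archetype: str
    period: float | None = None  # minutes; drawn per archetype when None
    duty: float = 0.5  # active-phase share of the period, in (0, 1)
    baseline: float = 1.0  # ratio units
    amplitude: float = 0.5  # ratio units
    drift_slope: float = 0.0  # ratio units / min
    noise_sd: float = 0.0  # ratio units
    fast_period: float = 1.0  # minutes; fast component of 'mixed'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in _ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.period is not None and self.period <= 0:
            raise ValueError("period must be positive")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must lie in (0, 1)")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")


def _logistic_square(t: np.ndarray, period: float, duty: float, edge_frac: float = 0.01) -> np.ndarray:
    """Periodic 0/1 burst train with logistic edges.

    The 50% crossing sits exactly at the programmed rise/fall times, so the
    empirical duty (fraction of samples above the midline) matches ``duty``
    to within one frame per cycle for any sampling finer than the edges.
    """
    tau = max(edge_frac * period, 1e-9)
    k_lo = int(np.floor(t.min() / period)) - 1
    k_hi = int(np.ceil(t.max() / period)) + 1
    out = np.zeros_like(t)
    for k in range(k_lo, k_hi + 1):
        rise = k * period
        fall = rise + duty * period
        # clip the logistic argument to keep exp() in range
        a = np.clip((t - rise) / tau, -60, 60)
        b = np.clip((t - fall) / tau, -60, 60)
        out += 1.0 / (1.0 + np.exp(-a)) - 1.0 / (1.0 + np.exp(-b))
    return out


def make_trace(
    spec: WaveSpec,
    segment_length: float = 40.0,
    sampling_interval: float = 0.1,
    t_start: float = 0.0,
    islet_id: str = "synthetic",
) -> Trace:
    """Synthesize one condition segment for one islet.

    Oscillating archetypes are rectified square-like waves with the
    requested period/duty plus linear drift and i.i.d. Gaussian noise.
    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(segment_length / sampling_interval))
    t = t_start + np.arange(n) * sampling_interval
    rel = t - t_start

    period = spec.period
    if spec.archetype in ("slow", "fast", "mixed") and period is None:
        period = float(rng.uniform(2.0, 10.0) if spec.archetype != "fast" else rng.uniform(0.5, 2.0))
    if spec.archetype in ("slow", "fast", "mixed"):
        assert period is not None
        if period <= 2.0 * sampling_interval:
            raise ValueError("period must exceed twice the sampling interval")

    if spec.archetype == "plateau":
        shape = np.ones(n)
        signal = spec.baseline + spec.amplitude * shape
    elif spec.archetype == "silent":
        signal = np.full(n, spec.baseline)
    elif spec.archetype == "mixed":
        slow = _logistic_square(rel, period, spec.duty)
        fast = _logistic_square(rel, spec.fast_period, 0.5)
        signal = spec.baseline + spec.amplitude * (2.0 * slow + fast) / 3.0
    else:
        signal = spec.baseline + spec.amplitude * _logistic_square(rel, period, spec.duty)

    signal = signal + spec.drift_slope * rel
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=n)
    return Trace(islet_id=islet_id, time=t, values=signal)


@dataclass(frozen=True)
class CohortSpec:
    """Strain-by-sex cohort layout plus per-strain archetype assignments.

    ``archetype_map`` maps each strain either to a single :class:`WaveSpec`
    (applied to every segment) or to one WaveSpec per segment.
    """

    strains: tuple[str, ...]
    sexes: tuple[str, ...] = ("M", "F")
    animals_per_group: int = 3
    islets_per_animal: int = 5
    archetype_map: dict = field(default_factory=dict)
    sampling_interval: float = 0.1  # minutes (6 s)
    segment_length: float = 40.0  # minutes
    n_segments: int = 4
    segment_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        frames = self.segment_length / self.sampling_interval
        if abs(frames - round(frames)) > 1e-9:
            raise ValueError("segment_length must be an integer number of frames")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.segment_labels is not None:
            if len(self.segment_labels) != self.n_segments:
                raise ValueError("segment_labels length must equal n_segments")
            return self.segment_labels
        if self.n_segments == 4:
            return ("8G", "8G_QLA", "8G_QLA_GIP", "2G")
        return tuple(f"seg{i}" for i in range(self.n_segments))

    def schedule(self) -> SegmentSchedule:
        L = self.segment_length
        return SegmentSchedule([(lab, i * L, (i + 1) * L) for i, lab in enumerate(self.labels)])


def _segment_specs(spec: CohortSpec, strain: str) -> list[WaveSpec]:
    try:
        entry = spec.archetype_map[strain]
    except KeyError as exc:
        raise ValueError(f"archetype_map is missing strain {strain!r}") from exc
    if isinstance(entry, WaveSpec):
        return [entry] * spec.n_segments
    entry = list(entry)
    if len(entry) != spec.n_segments:
        raise ValueError(
            f"strain {strain!r}: expected {spec.n_segments} per-segment wave specs, got {len(entry)}"
        )
    return entry


def _derived_seed(*keys: int) -> int:
    # counter-based derivation: any subset of islets is reproducible
    # independently of generation order
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def make_cohort(spec: CohortSpec) -> tuple[list[Trace], SegmentSchedule]:
    """Generate the full labeled cohort of traces.

    Per-islet, per-segment seeds derive deterministically from the cohort
    seed and the islet's position, so the cohort is a pure function of its
    spec and any sub-cohort can be regenerated in isolation.
    """
    schedule = spec.schedule()
    traces: list[Trace] = []
    islet_index = 0
    for strain in spec.strains:
        seg_specs = _segment_specs(spec, strain)
        for sex in spec.sexes:
            for a in range(1, spec.animals_per_group + 1):
                animal = f"{strain}_{sex}_{a}"
                for i in range(1, spec.islets_per_animal + 1):
                    islet_id = f"{animal}_{i}"
                    parts = []
                    for s_idx, (seg, wspec) in enumerate(zip(schedule, seg_specs)):
                        wspec = replace(
                            wspec, seed=_derived_seed(spec.seed, islet_index, s_idx)
                        )
                        parts.append(
                            make_trace(
                                wspec,
                                segment_length=seg.length,
                                sampling_interval=spec.sampling_interval,
                                t_start=seg.start,
                                islet_id=islet_id,
                            )
                        )
                    time = np.concatenate([p.time for p in parts])
                    values = np.concatenate([p.values for p in parts])
                    traces.append(
                        Trace(
                            islet_id=islet_id,
                            time=time,
                            values=values,
                            strain=strain,
                            sex=sex,
                            animal=animal,
                        )
                    )
                    islet_index += 1
    return traces, schedule


@dataclass(frozen=True)
class PlantSpec:
    """Protein-matrix plan: which proteins correlate with which parameters.

    ``planted`` entries are (protein_id, parameter_id, target_r); several
    entries may share one protein_id, in which case the protein is planted
    against the composite of those parameters and all its targets must share
    one value (attainable only when the parameters are mutually correlated).
    """

    n_proteins: int
    planted: tuple[tuple[str, str, float], ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pid, par, r in self.planted:
            if abs(r) > 1:
                raise ValueError(f"target_r for {pid!r}/{par!r} outside [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _zscore_np(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def make_protein_matrix(cohort_params: pd.DataFrame, spec: PlantSpec) -> pd.DataFrame:
    """Animal-by-protein abundance matrix with planted correlations.

    Each planted protein is the named parameter's Z-score (or, for
    multi-parameter plants, the unit-variance composite of the parameters'
    Z-scores) scaled by t and mixed with N(0, noise_sd) noise, with
    t = sigma * rho / sqrt(1 - rho^2) chosen so the expected Pearson r
    against each named parameter equals target_r.  Non-planted proteins are
    independent N(0, noise_sd) noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(cohort_params)
    by_protein: dict[str, list[tuple[str, float]]] = {}
    for pid, par, r in spec.planted:
        if par not in cohort_params.columns:
            raise ValueError(f"planted parameter {par!r} not in cohort_params")
        by_protein.setdefault(pid, []).append((par, r))

    cols: dict[str, np.ndarray] = {}
    planted_ids = list(by_protein)
    for pid in planted_ids:
        entries = by_protein[pid]
        targets = {round(abs(r), 12) for _, r in entries}
        if len(targets) > 1:
            raise ValueError(f"protein {pid!r}: multi-parameter plants need one |target_r|")
        zs = np.column_stack(
            [np.sign(r) * _zscore_np(cohort_params[par].to_numpy(float)) for par, r in entries]
        )
        composite = _zscore_np(zs.sum(axis=1))
        # attenuation of the composite against each individual parameter
        atten = float(np.mean([np.corrcoef(composite, zs[:, j])[0, 1] for j in range(zs.shape[1])]))
        rho = abs(entries[0][1])
        rho_c = rho / atten
        if rho_c > 1:
            raise ValueError(
                f"protein {pid!r}: per-parameter |r|={rho} unattainable; parameters too weakly correlated"
            )
        if rho_c == 1.0:
            cols[pid] = composite.copy()
        elif spec.noise_sd == 0:
            # scaling alone cannot lower a correlation; attenuation needs noise
            raise ValueError(
                f"protein {pid!r}: |target_r| < maximum requires noise_sd > 0"
            )
        else:
            t = spec.noise_sd * rho_c / np.sqrt(1.0 - rho_c**2)
            cols[pid] = t * composite + rng.normal(0.0, spec.noise_sd, size=n)
    n_null = spec.n_proteins - len(planted_ids)
    if n_null < 0:
        raise ValueError("n_proteins smaller than the number of planted proteins")
    for j in range(n_null):
        cols[f"null_{j + 1}"] = rng.normal(0.0, spec.noise_sd, size=n)
    return pd.DataFrame(cols, index=cohort_params.index)


def make_planted_cohort_params(
    n_animals: int = 16,
    block_params: tuple[str, ...] = ("8G_active_min", "8G_pulse_min", "8G_silent_min"),
    other_params: tuple[str, ...] = ("2G_avg", "8G_QLA_silent_min", "8G_QLA_GIP_silent_min"),
    block_r: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Animal-level parameter table with one correlated trait block.

    The block parameters share a latent factor with *empirical* pairwise
    correlation exactly ``block_r`` (built from QR-orthonormalized noise so
    the sample, not just the population, has the intended structure),
    mirroring the near-identical correlation structure of the 8G
    active/pulse/silent durations in real islet data; the remaining
    parameters are independent draws.  Used as the substrate for
    planted-protein recovery fixtures.
    """
    rng = np.random.default_rng(seed)
    k = len(block_params)
    raw = rng.normal(size=(n_animals, k + 1))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    basis = q * np.sqrt(n_animals - 1)  # mean-zero, unit sample SD, orthogonal
    latent, noise = basis[:, 0], basis[:, 1:]
    lam = np.sqrt(block_r)
    cols = {
        par: lam * latent + np.sqrt(1 - block_r) * noise[:, j]
        for j, par in enumerate(block_params)
    }
    for par in other_params:
        cols[par] = rng.normal(size=n_animals)
    idx = pd.Index([f"animal_{i + 1}" for i in range(n_animals)], name="animal")
    return pd.DataFrame(cols, index=idx)


def make_genomic_fixtures(
    n_genes: int,
    n_snps: int,
    n_loops: int,
    seed: int = 0,
    chrom: str = "chr1",
    window_bp: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Toy gene/SNP/loop fixtures on one synthetic chromosome.

    Genes are non-overlapping, spaced widely enough that their +/-window
    flanks never collide.  SNPs are placed at controlled offsets cycling
    through {gene body, inside flank, outside flank}; loops connect gene
    promoters to distal anchors 500 kbp downstream, each holding one
    dedicated SNP.  Deterministic per seed.
    """
    if min(n_genes, n_snps, n_loops) < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    spacing = 2 * window_bp + 800_000
    genes = []
    for g in range(n_genes):
        start = 1_000_000 + g * spacing + int(rng.integers(0, 10_000))
        length = int(rng.integers(20_000, 60_000))
        genes.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "gene_id": f"GENE{g + 1}",
                "score": 0,
                "strand": "+" if g % 2 == 0 else "-",
            }
        )
    genes_df = pd.DataFrame(
        genes, columns=["chrom", "start", "end", "gene_id", "score", "strand"]
    )

    snps = []
    for s in range(n_snps):
        if n_genes == 0:
            pos1 = int(rng.integers(1, 10_000_000))
        else:
            g = genes[s % n_genes]
            kind = (s // max(n_genes, 1)) % 3
            if kind == 0:  # in body
                pos1 = (g["start"] + g["end"]) // 2 + 1
            elif kind == 1:  # inside the flank
                pos1 = g["end"] + int(rng.integers(1, window_bp))
            else:  # outside the flank (still clear of the next gene's window)
                pos1 = g["end"] + window_bp + int(rng.integers(10_000, 200_000))
        snps.append(
            {
                "chrom": chrom,
                "pos": pos1,
                "rsid": f"rs{s + 1}",
                "pvalue": float(10.0 ** -rng.uniform(9, 12)) if s % 2 == 0 else 1e-6,
                "trait": GLYCEMIC_TRAITS[s % len(GLYCEMIC_TRAITS)],
            }
        )
    snps_df = pd.DataFrame(snps, columns=["chrom", "pos", "rsid", "pvalue", "trait"])

    loops = []
    extra_snps = []
    for l in range(min(n_loops, n_genes)):
        g = genes[l]
        tss = g["start"] if g["strand"] == "+" else g["end"]
        distal_start = g["end"] + 500_000
        loops.append(
            {
                "chrom_a": chrom,
                "start_a": max(tss - 2_000, 0),
                "end_a": tss + 2_000,
                "chrom_b": chrom,
                "start_b": distal_start,
                "end_b": distal_start + 10_000,
            }
        )
        extra_snps.append(
            {
                "chrom": chrom,
                "pos": distal_start + 5_000 + 1,
                "rsid": f"rs_loop{l + 1}",
                "pvalue": 1e-10,
                "trait": GLYCEMIC_TRAITS[l % len(GLYCEMIC_TRAITS)],
            }
        )
    loops_df = pd.DataFrame(
        loops, columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"]
    )
    if extra_snps:
        extra_df = pd.DataFrame(extra_snps, columns=snps_df.columns)
        snps_df = extra_df if snps_df.empty else pd.concat([snps_df, extra_df], ignore_index=True)
    return genes_df, snps_df, loops_df


def make_nomination_demo() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Three-gene fixture exercising every assignment route.

    GENE_WIN carries a significant SNP inside its 100-kbp flank; GENE_LOOP
    has no nearby SNP but loops to a distal anchor holding one; GENE_FAR has
    only an out-of-window, non-looped SNP.  Expected nominations at the
    default window/cutoff: exactly {GENE_WIN (window), GENE_LOOP (loop)}.
    """
    chrom = "chr1"
    genes = pd.DataFrame(
        [
            (chrom, 1_000_000, 1_050_000, "GENE_WIN", 0, "+"),
            (chrom, 5_000_000, 5_040_000, "GENE_LOOP", 0, "+"),
            (chrom, 9_000_000, 9_030_000, "GENE_FAR", 0, "+"),
        ],
        columns=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    snps = pd.DataFrame(
        [
            (chrom, 1_050_000 + 50_000, "rs_win", 1e-10, "T2D"),  # inside flank
            (chrom, 5_540_000 + 5_000 + 1, "rs_loop", 1e-11, "fasting_insulin"),  # in distal anchor
            (chrom, 9_030_000 + 100_001 + 1, "rs_far", 1e-12, "HbA1c"),  # outside flank
        ],
        columns=["chrom", "pos", "rsid", "pvalue", "trait"],
    )
    loops = pd.DataFrame(
        [(chrom, 4_998_000, 5_002_000, chrom, 5_540_000, 5_550_000)],
        columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"],
    )
    return genes, snps, loops
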