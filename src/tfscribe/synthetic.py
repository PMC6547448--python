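"""Synthetic ground-truth data emulating processed ChIP-exo / RNA-seq inputs.

The generator produces, from a :class:`SyntheticTruth` parameter record:

* promoter binding matrices (genes x TFs, one per condition) with log-normal
  marginals and designated collinear TF pairs at a target Pearson correlation
  (Gaussian copula on the log scale, correlation-matched to the target on the
  natural scale);
* expression responses built additively from linear, hinge (threshold) and
  saturating per-TF effects plus an optional multiplicative pair interaction
  and Gaussian noise, clipped at zero;
* pseudo-count tables that invert the FPKM formula (fixed library size,
  uniform gene lengths) so the counts -> FPKM path is exercised end to end;
* raw-style per-base coverage tracks with rectangular read pileups at known
  offsets over Poisson background.

Determinism: every quantity derives from ``truth.seed`` through fixed
counter-based child streams, so an identical truth yields a bit-identical
bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chip import CoverageTrack, PromoterSignalMatrix, TSSRecord

DEFAULT_CONDITIONS = ("nitrogen_lim", "glucose_lim", "anaerobic", "ethanol_lim")

# stream ids for counter-based child seeding
_STREAM_BINDING = 0
_STREAM_EXPRESSION = 1
_STREAM_TRACKS = 2
_STREAM_LENGTHS = 3


@dataclass
class SyntheticTruth:
    """Generative parameters: the ground truth that recovery tests assert against.

    Per-TF effects on expression are linear (``coefficients`` only), hinge
    (``knots[tf]`` gives the binding threshold below which the TF has no
    effect) or saturating (``saturation_knots[tf]`` gives a second threshold
    above which the effect plateaus).
    """

    n_genes: int = 850
    n_tfs: int = 21
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    active_tfs: tuple[int, ...] = ()
    coefficients: dict[int, float] = field(default_factory=dict)
    knots: dict[int, float] = field(default_factory=dict)
    saturation_knots: dict[int, float] = field(default_factory=dict)
    collinear_pairs: tuple[tuple[int, int, float], ...] = ()
    interaction_pair: tuple[int, int, float] | None = None
    intercept: float = 5.0
    noise_sd: float = 0.0
    binding_meanlog: float = 2.0
    binding_sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_tfs < 2:
            raise ValueError("n_tfs must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for tf in self.active_tfs:
            if not (0 <= tf < self.n_tfs):
                raise ValueError(f"active TF index {tf} out of range")
            if tf not in self.coefficients:
                raise ValueError(f"active TF {tf} has no coefficient")
        for a, b, rho in self.collinear_pairs:
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"collinear target rho {rho} outside [-1, 1]")
            if a == b:
                raise ValueError("collinear pair must be two distinct TFs")
        for tf, sat in self.saturation_knots.items():
            if tf in self.knots and sat <= self.knots[tf]:
                raise ValueError("saturation threshold must exceed the hinge knot")

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{k:02d}" for k in range(self.n_tfs)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene{g:04d}" for g in range(self.n_genes)]

    def rng(self, stream: int, index: int = 0) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream), int(index)])

    def to_json(self) -> str:
        d = asdict(self)
        d["coefficients"] = {str(k): v for k, v in self.coefficients.items()}
        d["knots"] = {str(k): v for k, v in self.knots.items()}
        d["saturation_knots"] = {str(k): v for k, v in self.saturation_knots.items()}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["conditions"] = tuple(d["conditions"])
        d["active_tfs"] = tuple(d["active_tfs"])
        d["coefficients"] = {int(k): v for k, v in d["coefficients"].items()}
        d["knots"] = {int(k): v for k, v in d["knots"].items()}
        d["saturation_knots"] = {int(k): v for k, v in d["saturation_knots"].items()}
        d["collinear_pairs"] = tuple(tuple(p) for p in d["collinear_pairs"])
        if d["interaction_pair"] is not None:
            d["interaction_pair"] = tuple(d["interaction_pair"])
        return cls(**d)


def default_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """The study-scale default: 850 metabolic genes, 21 TFs, 4 conditions.

    Six active TFs with positive (activating) effects, most behind a hinge
    threshold and one saturating, one strongly collinear pair (rho = 0.9) of
    which one member is a driver, and one multiplicative interaction pair.
    Noise is set so the generating model explains a realistic minority share
    of expression variance (around 0.4 at these settings).
    """
    params = dict(
        n_genes=850,
        n_tfs=21,
        conditions=DEFAULT_CONDITIONS,
        active_tfs=(0, 2, 5, 8, 12, 16),
        coefficients={0: 1.2, 2: 0.8, 5: 1.0, 8: 0.6, 12: 0.9, 16: 0.7},
        knots={0: 8.0, 2: 6.0, 5: 10.0, 12: 7.0},
        saturation_knots={5: 60.0},
        collinear_pairs=((2, 3, 0.9),),
        interaction_pair=(0, 2, 0.02),
        intercept=5.0,
        noise_sd=46.0,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticTruth(**params)


# ---------------------------------------------------------------------------
# Binding
# ---------------------------------------------------------------------------

def _log_scale_rho(target_rho: float, sdlog: float) -> float:
    """Gaussian-copula correlation giving Pearson ``target_rho`` between the
    log-normal marginals: rho_z = ln(1 + rho*(e^{s^2}-1)) / s^2, clipped."""
    s2 = sdlog**2
    arg = 1.0 + target_rho * np.expm1(s2)
    if arg <= 0:
        warnings.warn(f"target rho {target_rho} unreachable for log-normal marginals; clipping")
        return -1.0
    return float(np.clip(np.log(arg) / s2, -1.0, 1.0))


def generate_binding_matrix(truth: SyntheticTruth, condition: str) -> PromoterSignalMatrix:
    """Draw the genes x TFs promoter-signal matrix for one condition.

    Marginals are log-normal(meanlog, sdlog); each designated collinear pair
    is induced through a correlated Gaussian on the log scale so its
    empirical Pearson correlation lands on the target rho.
    """
    cond_idx = list(truth.conditions).index(condition)
    rng = truth.rng(_STREAM_BINDING, cond_idx)
    n, p = truth.n_genes, truth.n_tfs
    Z = rng.standard_normal((n, p))
    for a, b, rho in truth.collinear_pairs:
        rz = _log_scale_rho(rho, truth.binding_sdlog)
        za = Z[:, a].copy()
        Z[:, b] = rz * za + np.sqrt(max(0.0, 1 - rz**2)) * Z[:, b]
    X = np.exp(truth.binding_meanlog + truth.binding_sdlog * Z)
    df = pd.DataFrame(X, index=truth.gene_ids, columns=truth.tf_names)
    return PromoterSignalMatrix(values=df, condition=condition, representation="promoter_sum")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def tf_effect(truth: SyntheticTruth, tf: int, x: np.ndarray) -> np.ndarray:
    """The per-TF contribution f_k(x): linear, hinge, or saturating ramp."""
    beta = truth.coefficients[tf]
    knot = truth.knots.get(tf)
    sat = truth.saturation_knots.get(tf)
    if knot is None and sat is None:
        return beta * x
    t = knot if knot is not None else 0.0
    ramp = np.maximum(0.0, x - t)
    if sat is not None:
        ramp = np.minimum(ramp, sat - t)
    return beta * ramp


def generate_expression(truth: SyntheticTruth, binding: PromoterSignalMatrix) -> pd.Series:
    """Expression response for one condition's binding matrix.

    Y_i = b0 + sum_k f_k(X_ki) + gamma * X_ai * X_bi + eps_i, eps ~ N(0, sd),
    clipped at zero (FPKM scale).
    """
    if binding.values.shape != (truth.n_genes, truth.n_tfs):
        raise ValueError(
            f"binding shape {binding.values.shape} does not match truth "
            f"({truth.n_genes}, {truth.n_tfs})"
        )
    cond_idx = list(truth.conditions).index(binding.condition)
    rng = truth.rng(_STREAM_EXPRESSION, cond_idx)
    X = binding.values.to_numpy(dtype=float)
    y = np.full(truth.n_genes, truth.intercept, dtype=float)
    for tf in truth.active_tfs:
        y += tf_effect(truth, tf, X[:, tf])
    if truth.interaction_pair is not None:
        a, b, gamma = truth.interaction_pair
        y += gamma * X[:, a] * X[:, b]
    if truth.noise_sd > 0:
        y += rng.normal(0.0, truth.noise_sd, size=truth.n_genes)
    y = np.maximum(y, 0.0)
    return pd.Series(y, index=binding.genes, name=binding.condition)


def noise_free_signal(truth: SyntheticTruth, binding: PromoterSignalMatrix) -> pd.Series:
    """The deterministic part of the response (eps = 0, no clipping)."""
    X = binding.values.to_numpy(dtype=float)
    y = np.full(truth.n_genes, truth.intercept, dtype=float)
    for tf in truth.active_tfs:
        y += tf_effect(truth, tf, X[:, tf])
    if truth.interaction_pair is not None:
        a, b, gamma = truth.interaction_pair
        y += gamma * X[:, a] * X[:, b]
    return pd.Series(y, index=binding.genes)


# ---------------------------------------------------------------------------
# Pseudo-counts (inverse FPKM)
# ---------------------------------------------------------------------------

def gene_lengths(truth: SyntheticTruth) -> pd.Series:
    """Gene lengths, uniform in [500, 5000] bp, deterministic per truth."""
    rng = truth.rng(_STREAM_LENGTHS)
    lengths = rng.integers(500, 5001, size=truth.n_genes)
    return pd.Series(lengths, index=truth.gene_ids, name="length_bp")


def expression_to_counts(
    fpkm_by_condition: pd.DataFrame,
    lengths: pd.Series,
    library_size: float = 1e7,
    replicates: int = 3,
) -> pd.DataFrame:
    """Invert the FPKM formula into a replicate-expanded pseudo-count table.

    count = fpkm * library_size * length / 1e9, identical across replicates;
    the expression noise already lives in the FPKM response.
    """
    counts = {}
    for cond in fpkm_by_condition.columns:
        c = fpkm_by_condition[cond] * library_size * lengths / 1e9
        for rep in range(1, replicates + 1):
            counts[f"{cond}.rep{rep}"] = c
    out = pd.DataFrame(counts, index=fpkm_by_condition.index)
    out.insert(0, "length_bp", lengths)
    return out


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

def make_tss_table(
    gene_ids: Sequence[str],
    chrom: str = "chrS",
    spacing: int = 3000,
    first_tss: int = 2000,
) -> list[TSSRecord]:
    """Evenly spaced TSSs on one synthetic chromosome, alternating strand."""
    return [
        TSSRecord(gene_id=g, chrom=chrom, tss=first_tss + i * spacing, strand="+-"[i % 2])
        for i, g in enumerate(gene_ids)
    ]


def generate_coverage_track(
    tss: Sequence[TSSRecord],
    peak_offsets: Mapping[str, Sequence[int]],
    peak_heights: Mapping[str, Sequence[float]],
    background_rate: float = 0.0,
    peak_width: int = 10,
    chrom_lengths: Mapping[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> CoverageTrack:
    """Background Poisson noise plus rectangular read pileups at known offsets.

    ``peak_offsets[gene]`` are positions relative to the TSS in gene
    orientation (negative = upstream); they are mirrored onto the genome for
    minus-strand genes.  Each pileup adds ``height`` reads per base over
    ``peak_width`` bases centered on the peak position.
    """
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    rng = rng or np.random.default_rng(0)
    by_chrom: dict[str, list[TSSRecord]] = {}
    for rec in tss:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    if chrom_lengths is None:
        chrom_lengths = {
            c: max(r.tss for r in recs) + 3000 for c, recs in by_chrom.items()
        }
    coverage = {}
    for chrom, length in chrom_lengths.items():
        if background_rate > 0:
            vec = rng.poisson(background_rate, size=length).astype(float)
        else:
            vec = np.zeros(length, dtype=float)
        for rec in by_chrom.get(chrom, ()):
            offs = peak_offsets.get(rec.gene_id, ())
            hts = peak_heights.get(rec.gene_id, ())
            if len(offs) != len(hts):
                raise ValueError(f"offset/height length mismatch for {rec.gene_id}")
            for off, h in zip(offs, hts):
                if h < 0:
                    raise ValueError("negative peak height")
                if abs(off) > 2000:
                    raise ValueError(f"peak offset {off} outside +/-2000 bp of TSS")
                center = rec.tss + off if rec.strand == "+" else rec.tss - off
                half = peak_width // 2
                lo = max(center - half, 1)
                hi = min(center - half + peak_width - 1, length)
                if hi >= lo:
                    vec[lo - 1 : hi] += h
        coverage[chrom] = vec
    return CoverageTrack(coverage)


def binding_to_tracks(
    truth: SyntheticTruth,
    binding: PromoterSignalMatrix,
    tss: Sequence[TSSRecord],
    tf: str,
    peak_offset: int = -100,
    peak_width: int = 10,
    background_rate: float = 0.05,
    replicates: int = 2,
) -> list[CoverageTrack]:
    """Replicate coverage tracks for one TF whose promoter sums recover the
    binding matrix column (peak height = binding / width), with independent
    Poisson background per replicate."""
    col = binding.values[tf]
    offsets = {g: [peak_offset] for g in col.index}
    heights = {g: [v / peak_width] for g, v in col.items()}
    cond_idx = list(truth.conditions).index(binding.condition)
    tf_idx = truth.tf_names.index(tf)
    tracks = []
    for rep in range(replicates):
        rng = truth.rng(_STREAM_TRACKS, cond_idx * 10_000 + tf_idx * 10 + rep)
        tracks.append(
            generate_coverage_track(
                tss, offsets, heights, background_rate=background_rate,
                peak_width=peak_width, rng=rng,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """Everything a downstream stage needs, with the truth that made it."""

    truth: SyntheticTruth
    binding: dict[str, PromoterSignalMatrix]
    expression: pd.DataFrame  # genes x conditions, FPKM scale
    counts: pd.DataFrame  # gene_id x (length_bp, condition.rep columns)
    tss: list[TSSRecord]

    def __post_init__(self) -> None:
        genes = set(self.expression.index)
        for cond, mat in self.binding.items():
            if set(mat.genes) != genes:
                raise ValueError(f"gene universe mismatch in condition {cond}")
        if {t.gene_id for t in self.tss} != genes:
            raise ValueError("TSS table does not cover the gene universe")


def generate_bundle(truth: SyntheticTruth) -> SyntheticBundle:
    """Binding, expression, pseudo-counts and TSS table for every condition."""
    binding = {c: generate_binding_matrix(truth, c) for c in truth.conditions}
    expression = pd.DataFrame(
        {c: generate_expression(truth, binding[c]) for c in truth.conditions}
    )
    counts = expression_to_counts(expression, gene_lengths(truth))
    tss = make_tss_table(truth.gene_ids)
    return SyntheticBundle(truth=truth, binding=binding, expression=expression, counts=counts, tss=tss)
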