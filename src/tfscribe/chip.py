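"""Quantification of ChIP-exo coverage into per-gene TF binding signal.

A :class:`CoverageTrack` holds dense per-base read counts for one TF in one
condition (1-based coordinates, as in the WIG format).  Three representations
of promoter binding are derived from it:

``promoter_sum``
    Total read count in a fixed window around the TSS (default -500..+500,
    1001 bases inclusive).
``peak_window``
    Read count summed in +/-50 bp windows around detected peaks annotated to
    the gene.
``peak_signal``
    Sum of summit signal of annotated peaks passing a signal-to-noise
    threshold (a naive stand-in detector for a dedicated event caller).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class WigParseError(ValueError):
    """Raised when a WIG file cannot be parsed; message names the line."""


@dataclass
class CoverageTrack:
    """Dense per-base coverage, one vector per chromosome, 1-based inclusive.

    ``coverage[chrom][i]`` is the read count at 1-based position ``i + 1``.
    """

    coverage: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, vec in self.coverage.items():
            arr = np.asarray(vec, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.coverage[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self.coverage)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.coverage.values()))

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return self.coverage.keys() == other.coverage.keys() and all(
            np.array_equal(self.coverage[c], other.coverage[c]) for c in self.coverage
        )


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: gene id, chromosome, 1-based coordinate, strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"TSS must be >= 1, got {self.tss} for {self.gene_id}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class Peak:
    """A detected binding event with its local-background signal-to-noise ratio."""

    chrom: str
    position: int  # 1-based summit
    signal: float
    local_noise: float
    snr: float
    gene_id: str | None = None


# ---------------------------------------------------------------------------
# WIG I/O
# ---------------------------------------------------------------------------

def read_wig(path) -> CoverageTrack:
    """Parse a fixedStep or variableStep WIG file into a dense track.

    Positions not covered by any declaration are 0.  Malformed headers raise
    :class:`WigParseError` naming the offending line number.
    """
    chrom_vals: dict[str, dict[int, float]] = {}
    mode = None  # ("fixed", chrom, next_pos, step, span) or ("variable", chrom, span)
    n_data = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = _wig_header_fields(line, lineno)
                try:
                    chrom = fields["chrom"]
                    start = int(fields["start"])
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                except (KeyError, ValueError) as exc:
                    raise WigParseError(f"line {lineno}: bad fixedStep header: {exc}")
                mode = ["fixed", chrom, start, step, span]
                chrom_vals.setdefault(chrom, {})
            elif line.startswith("variableStep"):
                fields = _wig_header_fields(line, lineno)
                try:
                    chrom = fields["chrom"]
                    span = int(fields.get("span", 1))
                except (KeyError, ValueError) as exc:
                    raise WigParseError(f"line {lineno}: bad variableStep header: {exc}")
                mode = ["variable", chrom, span]
                chrom_vals.setdefault(chrom, {})
            else:
                if mode is None:
                    raise WigParseError(f"line {lineno}: data before any step header")
                parts = line.split()
                try:
                    if mode[0] == "fixed":
                        (value,) = parts
                        pos, span = mode[2], mode[4]
                        _wig_fill(chrom_vals[mode[1]], pos, span, float(value), lineno)
                        mode[2] = pos + mode[3]
                    else:
                        pos_s, value = parts
                        pos, span = int(pos_s), mode[2]
                        _wig_fill(chrom_vals[mode[1]], pos, span, float(value), lineno)
                except ValueError as exc:
                    raise WigParseError(f"line {lineno}: bad data line {line!r}: {exc}")
                n_data += 1
    if n_data == 0:
        raise WigParseError(f"{path}: no data lines found")
    coverage = {}
    for chrom, vals in chrom_vals.items():
        length = max(vals)
        vec = np.zeros(length, dtype=float)
        for pos, v in vals.items():
            vec[pos - 1] = v
        coverage[chrom] = vec
    return CoverageTrack(coverage)


def _wig_header_fields(line: str, lineno: int) -> dict[str, str]:
    fields = {}
    for tok in line.split()[1:]:
        if "=" not in tok:
            raise WigParseError(f"line {lineno}: malformed header token {tok!r}")
        k, v = tok.split("=", 1)
        fields[k] = v
    return fields


def _wig_fill(store: dict[int, float], pos: int, span: int, value: float, lineno: int) -> None:
    if pos < 1:
        raise ValueError(f"position {pos} < 1")
    for p in range(pos, pos + span):
        if p in store:
            raise WigParseError(f"line {lineno}: overlapping declaration at position {p}")
        store[p] = value


def write_wig(track: CoverageTrack, path, name: str | None = None) -> None:
    """Write a track as fixedStep step=1 WIG (lossless with :func:`read_wig`)."""
    with open(path, "w") as fh:
        if name:
            fh.write(f"track type=wiggle_0 name={name}\n")
        for chrom in track.chroms:
            fh.write(f"fixedStep chrom={chrom} start=1 step=1 span=1\n")
            vec = track.coverage[chrom]
            fh.write("\n".join(format(v, "g") for v in vec))
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSS tables
# ---------------------------------------------------------------------------

def read_tss_table(path) -> list[TSSRecord]:
    """Read a BED-like TSS table (chrom, tss_pos, gene_id, strand; one header line)."""
    df = pd.read_csv(path, sep="\t")
    return [
        TSSRecord(gene_id=str(r.gene_id), chrom=str(r.chrom), tss=int(r.tss_pos), strand=str(r.strand))
        for r in df.itertuples()
    ]


def write_tss_table(tss: Sequence[TSSRecord], path) -> None:
    pd.DataFrame(
        {
            "chrom": [t.chrom for t in tss],
            "tss_pos": [t.tss for t in tss],
            "gene_id": [t.gene_id for t in tss],
            "strand": [t.strand for t in tss],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def average_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Per-base arithmetic mean of replicate tracks (chromosome sets must match)."""
    if not tracks:
        raise ValueError("no tracks to average")
    ref = tracks[0]
    for t in tracks[1:]:
        if set(t.chroms) != set(ref.chroms):
            raise ValueError("replicate tracks have different chromosome sets")
        for c in ref.chroms:
            if len(t.coverage[c]) != len(ref.coverage[c]):
                raise ValueError(f"replicate length mismatch on {c}")
    out = {
        c: np.mean([t.coverage[c] for t in tracks], axis=0) for c in ref.chroms
    }
    return CoverageTrack(out)


def _window_bounds(rec: TSSRecord, upstream: int, downstream: int, mirror: bool) -> tuple[int, int]:
    """1-based inclusive genomic window for a gene, strand-mirrored by default."""
    if rec.strand == "+" or not mirror:
        return rec.tss - upstream, rec.tss + downstream
    return rec.tss - downstream, rec.tss + upstream


def promoter_sum(
    track: CoverageTrack,
    tss: Sequence[TSSRecord],
    window: tuple[int, int] = (500, 500),
    mirror_strand: bool = True,
) -> pd.Series:
    """Total coverage in the promoter window of each gene.

    The window is inclusive on both ends: the default (500, 500) spans 1001
    bases.  For minus-strand genes the window is mirrored so that "upstream"
    is 5' of the gene; pass ``mirror_strand=False`` for strand-agnostic
    windows.  Positions outside the chromosome contribute 0; genes on unknown
    chromosomes get NaN with a warning.
    """
    up, down = window
    if up < 0 or down < 0:
        raise ValueError("window bounds must be >= 0")
    out = {}
    missing = []
    for rec in tss:
        vec = track.coverage.get(rec.chrom)
        if vec is None:
            missing.append(rec.gene_id)
            out[rec.gene_id] = np.nan
            continue
        lo, hi = _window_bounds(rec, up, down, mirror_strand)
        lo = max(lo, 1)
        hi = min(hi, len(vec))
        out[rec.gene_id] = float(vec[lo - 1 : hi].sum()) if hi >= lo else 0.0
    if missing:
        warnings.warn(f"unknown chromosome for {len(missing)} genes (e.g. {missing[0]})")
    return pd.Series(out, name="promoter_sum")


def detect_peaks(
    track: CoverageTrack,
    min_snr: float = 2.0,
    noise_window_bp: int = 2000,
    smooth_bp: int = 5,
) -> list[Peak]:
    """Naive local-maximum peak detector with a local-noise SNR filter.

    Coverage is smoothed with a centered moving average, local maxima are
    located, and each candidate's local noise is the median coverage in
    ``noise_window_bp`` flanking each side, excluding the peak span (the
    contiguous region at >= half the summit height).  Peaks are retained when
    ``signal / local_noise > min_snr`` (strict).
    """
    from scipy.signal import find_peaks as _find_peaks

    if noise_window_bp <= 0:
        raise ValueError("noise_window_bp must be > 0")
    peaks: list[Peak] = []
    for chrom, vec in track.coverage.items():
        if not vec.any():
            continue
        if smooth_bp > 1:
            kernel = np.ones(smooth_bp) / smooth_bp
            smooth = np.convolve(vec, kernel, mode="same")
        else:
            smooth = vec
        idx, _ = _find_peaks(smooth)
        # plateau summits (rectangular pileups) are missed by strict maxima:
        # add the midpoint of maximal runs
        idx = _add_plateau_summits(smooth, idx)
        for i in sorted(set(idx)):
            signal = float(vec[i])
            if signal <= 0:
                continue
            lo, hi = _peak_span(vec, i)
            left = vec[max(0, lo - noise_window_bp) : lo]
            right = vec[hi + 1 : hi + 1 + noise_window_bp]
            flank = np.concatenate([left, right])
            local_noise = float(np.median(flank)) if flank.size else 0.0
            snr = signal / local_noise if local_noise > 0 else np.inf
            if snr > min_snr:
                peaks.append(
                    Peak(chrom=chrom, position=i + 1, signal=signal, local_noise=local_noise, snr=snr)
                )
    return peaks


def _add_plateau_summits(vec: np.ndarray, idx: np.ndarray) -> list[int]:
    out = list(idx)
    n = len(vec)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and vec[j + 1] == vec[i]:
            j += 1
        if j > i and vec[i] > 0 and not (i == 0 and j == n - 1):
            left_ok = i == 0 or vec[i - 1] < vec[i]
            right_ok = j == n - 1 or vec[j + 1] < vec[i]
            if left_ok and right_ok:
                out.append((i + j) // 2)
        i = j + 1
    return out


def _peak_span(vec: np.ndarray, summit: int, max_half_span: int = 500) -> tuple[int, int]:
    # contiguous region at >= half the summit height, capped so a high
    # background cannot swallow the whole chromosome into the span
    half = vec[summit] / 2.0
    lo = summit
    while lo > 0 and vec[lo - 1] >= half and summit - lo < max_half_span:
        lo -= 1
    hi = summit
    while hi < len(vec) - 1 and vec[hi + 1] >= half and hi - summit < max_half_span:
        hi += 1
    return lo, hi


def annotate_peaks(
    peaks: Iterable[Peak], tss: Sequence[TSSRecord], radius_bp: int = 500
) -> list[Peak]:
    """Assign each peak to the gene whose TSS is within ``radius_bp`` (inclusive).

    The nearest TSS wins; exact distance ties go to the lexicographically
    smaller gene id.  Peaks with no TSS in range keep ``gene_id = None``.
    """
    if radius_bp < 0:
        raise ValueError("radius_bp must be >= 0")
    by_chrom: dict[str, list[TSSRecord]] = {}
    for rec in tss:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    out = []
    for p in peaks:
        best: tuple[int, str] | None = None
        for rec in by_chrom.get(p.chrom, ()):
            d = abs(rec.tss - p.position)
            if d <= radius_bp and (best is None or (d, rec.gene_id) < best):
                best = (d, rec.gene_id)
        out.append(replace(p, gene_id=best[1] if best else None))
    return out


def peak_window_sum(
    track: CoverageTrack,
    peaks: Sequence[Peak],
    tss: Sequence[TSSRecord],
    halfwidth_bp: int = 50,
) -> pd.Series:
    """Per-gene coverage summed in +/-halfwidth windows around annotated peaks.

    Overlapping windows of the same gene count each base once; genes without
    annotated peaks get 0.
    """
    gene_bases: dict[str, dict[str, set[int]]] = {}
    for p in peaks:
        if p.gene_id is None:
            continue
        gene_bases.setdefault(p.gene_id, {}).setdefault(p.chrom, set()).update(
            range(p.position - halfwidth_bp, p.position + halfwidth_bp + 1)
        )
    out = {}
    for rec in tss:
        total = 0.0
        for chrom, bases in gene_bases.get(rec.gene_id, {}).items():
            vec = track.coverage.get(chrom)
            if vec is None:
                continue
            ok = [b for b in bases if 1 <= b <= len(vec)]
            total += float(vec[np.array(ok, dtype=int) - 1].sum()) if ok else 0.0
        out[rec.gene_id] = total
    return pd.Series(out, name="peak_window_sum")


def peak_signal_sum(peaks: Sequence[Peak], tss: Sequence[TSSRecord]) -> pd.Series:
    """Per-gene sum of summit signal over annotated (SNR-passing) peaks."""
    out = {rec.gene_id: 0.0 for rec in tss}
    for p in peaks:
        if p.gene_id is not None and p.gene_id in out:
            out[p.gene_id] += p.signal
    return pd.Series(out, name="peak_signal")


def condition_targets(
    targets_by_condition: Mapping[str, Iterable[str]],
) -> dict:
    """Target-gene sets per condition plus exact overlap counts.

    ``targets_by_condition`` maps a condition label to the genes with at least
    one annotated SNR-passing peak.  Returns the per-condition sets and the
    cardinality of every nonempty combination of conditions (genes in exactly
    that combination), i.e. the regions of an Euler diagram.
    """
    from itertools import combinations

    sets = {c: set(g) for c, g in targets_by_condition.items()}
    if not sets:
        raise ValueError("need at least one condition")
    conds = sorted(sets)
    regions = {}
    for r in range(1, len(conds) + 1):
        for combo in combinations(conds, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[c] for c in conds if c not in combo))
            regions["&".join(combo)] = len(inside - outside)
    return {"targets": sets, "exclusive_overlaps": regions}


def build_signal_matrix(per_tf: Mapping[str, pd.Series], condition: str,
                        window: tuple[int, int] = (500, 500),
                        representation: str = "promoter_sum") -> "PromoterSignalMatrix":
    df = pd.DataFrame(per_tf)
    return PromoterSignalMatrix(values=df, condition=condition, window=window,
                                representation=representation)


@dataclass
class PromoterSignalMatrix:
    """Genes x TFs binding quantification: the regression design matrix."""

    values: pd.DataFrame  # rows = genes, columns = TFs
    condition: str
    window: tuple[int, int] = (500, 500)
    representation: str = "promoter_sum"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in signal matrix")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0) < 0:
            raise ValueError("negative binding signal")
        if self.representation not in {"promoter_sum", "peak_window", "peak_signal"}:
            raise ValueError(f"unknown representation {self.representation!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def tfs(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, condition: str = "", **kw) -> "PromoterSignalMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(values=df, condition=condition, **kw)
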