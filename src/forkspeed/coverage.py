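"""Binned sequencing-coverage tracks and stationary-phase bias correction.

Coverage enters as binned read counts (2-column TSV: bin index, count) or as
bedGraph intervals whose values are apportioned to 10-kbp bins by overlap.
Sequence-dependent coverage bias (GC content, mappability, library chemistry)
is multiplicative and shared between growth phases, so dividing each
exponential-phase bin frequency by the matching stationary-phase frequency
cancels it and leaves the replication signal. Bins with no usable stationary
signal are masked — no pseudocounts — and every downstream likelihood applies
the same mask to data and model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import GenomeGeometry

__all__ = [
    "CoverageTrack",
    "read_track",
    "write_track",
    "bias_correct",
    "cross_replicates",
    "to_origin_coordinates",
]


@dataclass
class CoverageTrack:
    """Per-bin read counts (or corrected pseudo-counts) on a genome geometry."""

    geometry: GenomeGeometry
    counts: np.ndarray
    phase: str
    replicate_id: str = ""
    temperature: float | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.geometry.n_bins,):
            raise ValueError(
                f"counts must have one entry per bin "
                f"({self.geometry.n_bins}), got shape {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.mask is None:
            self.mask = np.ones(self.geometry.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape must match counts")

    @property
    def total(self) -> float:
        return float(self.counts[self.mask].sum())

    def frequencies(self) -> np.ndarray:
        """Counts normalized over unmasked bins (masked bins set to 0)."""
        total = self.total
        if total <= 0:
            raise ValueError("track has no reads on unmasked bins")
        freq = np.where(self.mask, self.counts, 0.0) / total
        return freq


def read_track(
    path,
    geometry: GenomeGeometry,
    phase: str = "exponential",
    replicate_id: str = "",
    fmt: str | None = None,
    temperature: float | None = None,
) -> CoverageTrack:
    """Read a coverage file into geometry bins.

    ``fmt`` is ``"bedgraph"`` (chrom, start, end, value; 0-based half-open;
    interval counts split across bins in proportion to overlap) or ``"tsv"``
    (bin_index, count). When omitted it is inferred from the extension and,
    failing that, from the column count of the first data line.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in {".bedgraph", ".bg"}:
            fmt = "bedgraph"
        elif suffix in {".tsv", ".txt"}:
            fmt = None  # decide from the first data line
        else:
            fmt = None

    counts = np.zeros(geometry.n_bins)
    L = geometry.length_bp
    bin_bp = geometry.bin_bp
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser", "bin_index", "chrom\t")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if fmt is None:
                fmt = "bedgraph" if len(parts) >= 4 else "tsv"
            try:
                if fmt == "bedgraph":
                    start, end, value = float(parts[1]), float(parts[2]), float(parts[3])
                else:
                    idx, value = int(parts[0]), float(parts[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed line: {line!r}") from exc

            if fmt == "tsv":
                if not (0 <= idx < geometry.n_bins):
                    raise ValueError(f"{path.name}:{lineno}: bin index {idx} out of range")
                counts[idx] += value
                continue

            if not (0 <= start < end <= L):
                raise ValueError(
                    f"{path.name}:{lineno}: interval [{start}, {end}) outside [0, {L})"
                )
            first = int(start // bin_bp)
            last = min(int(np.ceil(end / bin_bp)), geometry.n_bins)
            span = end - start
            for b in range(first, last):
                lo = max(start, b * bin_bp)
                hi = min(end, min((b + 1) * bin_bp, L))
                if hi > lo:
                    counts[b] += value * (hi - lo) / span
    return CoverageTrack(
        geometry, counts, phase=phase, replicate_id=replicate_id, temperature=temperature
    )


def write_track(track: CoverageTrack, path) -> None:
    """Write a track as TSV (bin_index, count, mask) with a geometry header."""
    path = Path(path)
    g = track.geometry
    with path.open("w") as fh:
        fh.write(
            f"# length_bp={g.length_bp!r}\torigin_bp={g.origin_bp!r}"
            f"\tbin_bp={g.bin_bp!r}\tphase={track.phase}"
            f"\treplicate_id={track.replicate_id}\n"
        )
        fh.write("bin_index\tcount\tmask\n")
        for i, (c, m) in enumerate(zip(track.counts, track.mask)):
            fh.write(f"{i}\t{c:.10g}\t{int(m)}\n")


def bias_correct(
    exponential: CoverageTrack,
    stationary: CoverageTrack,
    min_stationary: float = 0.0,
) -> CoverageTrack:
    """Divide exponential-phase bin frequencies by stationary-phase ones.

    Any per-bin multiplicative bias shared by the two tracks cancels exactly.
    Bins whose stationary frequency is zero or below ``min_stationary`` are
    masked; the corrected frequencies are renormalized over the surviving
    bins and rescaled to pseudo-counts carrying the ratio estimator's
    effective read depth, N_eff = (1/N_exp + 1/N_stat)^-1, so that downstream
    multinomial likelihoods are calibrated to the true sampling variance of
    the corrected curve (both phases contribute counting noise). The result
    is invariant to rescaling either input by a positive constant.
    """
    if exponential.geometry != stationary.geometry:
        raise ValueError("tracks must share one geometry")
    if exponential.phase != "exponential" or stationary.phase != "stationary":
        raise ValueError(
            f"expected phases exponential/stationary, got "
            f"{exponential.phase}/{stationary.phase}"
        )
    base = exponential.mask & stationary.mask & (stationary.counts > 0)
    if not base.any():
        raise ValueError("all bins masked: no usable stationary signal")
    stat_freq = np.where(base, stationary.counts, 0.0) / stationary.counts[base].sum()
    mask = base & (stat_freq >= min_stationary) & (stat_freq > 0)
    if not mask.any():
        raise ValueError("all bins masked after applying min_stationary")
    stat_freq = np.where(mask, stationary.counts, 0.0) / stationary.counts[mask].sum()
    exp_freq = np.where(mask, exponential.counts, 0.0) / exponential.counts[mask].sum()
    ratio = np.zeros_like(exp_freq)
    ratio[mask] = exp_freq[mask] / stat_freq[mask]
    corrected = ratio / ratio[mask].sum()
    # effective depth of the ratio estimator: both phases contribute noise
    n_exp = exponential.counts[mask].sum()
    n_stat = stationary.counts[mask].sum()
    n_eff = 1.0 / (1.0 / n_exp + 1.0 / n_stat)
    pseudo = corrected * n_eff
    rep = f"{exponential.replicate_id}x{stationary.replicate_id}"
    return CoverageTrack(
        exponential.geometry,
        pseudo,
        phase="corrected",
        replicate_id=rep,
        temperature=exponential.temperature,
        mask=mask,
    )


def cross_replicates(
    exponentials: list[CoverageTrack],
    stationaries: list[CoverageTrack],
    min_stationary: float = 0.0,
) -> list[CoverageTrack]:
    """Bias-correct every (exponential, stationary) replicate pair.

    Three exponential and three stationary replicates yield nine corrected
    abundance curves, labelled ``expidxstatid``.
    """
    if not exponentials or not stationaries:
        raise ValueError("replicate lists must be non-empty")
    geometry = exponentials[0].geometry
    for track in [*exponentials, *stationaries]:
        if track.geometry != geometry:
            raise ValueError("all tracks must share one geometry")
    return [
        bias_correct(exp, stat, min_stationary=min_stationary)
        for exp in exponentials
        for stat in stationaries
    ]


def to_origin_coordinates(geometry: GenomeGeometry, linear_bp):
    """Signed origin distance y for linear reference position(s)."""
    return geometry.to_origin_coordinates(linear_bp)
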