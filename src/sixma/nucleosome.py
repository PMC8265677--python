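"""Nucleosome dyad profiles, positioning degree, periodicity, 6mA phasing.

Dyads are estimated as midpoints of mononucleosome-sized MNase fragments.
The positioning degree of the +k nucleosome is the contrast
(peak - trough) / (peak + trough) of the composite TSS-aligned dyad
profile, with peak and trough densities averaged over +/-20 bp around the
located extrema. This contrast statistic is this package's explicit,
testable definition; it is scale-invariant and 0 on a flat profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import bin_levels
from .genome_io import GeneModel, ParseError

logger = logging.getLogger(__name__)


@dataclass
class DyadProfile:
    """Area-normalized per-base dyad density over a TSS-aligned window."""

    positions: np.ndarray  # bp relative to TSS
    density: np.ndarray
    smooth: int
    n_dyads: int = 0
    n_genes: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "density": self.density})


@dataclass
class PositioningReport:
    """Peak locations and positioning degrees for +1..+k nucleosomes."""

    peaks: list[int]
    degrees: list[float]
    periodicity: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "peaks": self.peaks,
            "degrees": self.degrees,
            "periodicity": self.periodicity,
            "warnings": self.warnings,
        }


def read_bed_fragments(path) -> pd.DataFrame:
    """Plain 3+-column BED (0-based half-open) into chrom/start/end."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if start < 0 or end <= start:
                raise ParseError(f"{path}:{lineno}: bad interval [{start},{end})")
            rows.append((cols[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def fragments_to_dyads(fragments: pd.DataFrame, min_len: int = 120,
                       max_len: int = 180) -> pd.DataFrame:
    """Fragment midpoints, gated to mononucleosome-sized lengths.

    Fragments with length outside [min_len, max_len] are discarded (the
    count is logged); the dyad is floor((start+end)/2).
    """
    length = fragments["end"] - fragments["start"]
    keep = (length >= min_len) & (length <= max_len)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("length gate removed %d of %d fragments", n_drop, len(fragments))
    sub = fragments[keep]
    return pd.DataFrame(
        {"chrom": sub["chrom"].to_numpy(),
         "dyad": ((sub["start"] + sub["end"]) // 2).to_numpy()}
    )


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with reflected edges (area-preserving-ish)."""
    if width <= 1:
        return x.astype(float)
    pad = width // 2
    xp = np.pad(x.astype(float), pad, mode="reflect")
    kernel = np.ones(width) / width
    return np.convolve(xp, kernel, mode="valid")


def composite_dyad_profile(dyads: pd.DataFrame, genes: list[GeneModel],
                           window: tuple[int, int] = (-500, 1500),
                           smooth: int = 31) -> DyadProfile:
    """Strand-oriented dyad counts around TSS, smoothed and area-normalized."""
    if not genes:
        raise ValueError("no genes for composite profile")
    if smooth % 2 == 0:
        raise ValueError("smoothing width must be odd")
    lo, hi = window
    acc = np.zeros(hi - lo)
    n_used = 0
    by_chrom = {c: np.sort(g["dyad"].to_numpy()) for c, g in dyads.groupby("chrom", sort=False)}
    for gene in genes:
        pos = by_chrom.get(gene.chrom)
        if pos is None:
            continue
        if gene.strand == "+":
            glo, ghi = gene.tss + lo, gene.tss + hi
        else:
            glo, ghi = gene.tss - hi + 1, gene.tss - lo + 1
        i, j = np.searchsorted(pos, glo, "left"), np.searchsorted(pos, ghi, "left")
        p = pos[i:j]
        rel = (p - gene.tss) if gene.strand == "+" else (gene.tss - p)
        np.add.at(acc, rel - lo, 1.0)
        n_used += len(p)
    sm = _moving_average(acc, smooth)
    total = sm.sum()
    if total == 0:
        raise ValueError("no dyads within any TSS window")
    return DyadProfile(np.arange(lo, hi), sm / total, smooth, n_used, len(genes))


def _mean_around(density: np.ndarray, idx: int, half: int) -> float:
    lo, hi = max(0, idx - half), min(len(density), idx + half + 1)
    return float(density[lo:hi].mean())


def positioning_degree(profile: DyadProfile, k_max: int = 5,
                       spacing_guess: int = 200, search_width: int = 250,
                       avg_half: int = 20) -> PositioningReport:
    """Positioning degree of the +1..+k_max nucleosomes downstream of TSS.

    The +k peak is the profile maximum in [spacing*(k-1), spacing*(k-1) +
    search_width) bp downstream of the TSS. Troughs are minima between
    adjacent peaks, between the TSS and the +1 peak, and between the last
    peak and the window end. degree_k = (P_k - T_k) / (P_k + T_k) where
    P_k and T_k are mean densities within +/- ``avg_half`` bp of the peak
    and of its two flanking troughs (trough values averaged).
    """
    d = profile.density
    pos = profile.positions
    warnings: list[str] = []

    def at(rel_bp: int) -> int:  # window index of a TSS-relative coordinate
        return int(np.searchsorted(pos, rel_bp))

    peaks = []
    for k in range(1, k_max + 1):
        lo_bp = spacing_guess * (k - 1)
        hi_bp = min(lo_bp + search_width, int(pos[-1]) + 1)
        i, j = at(lo_bp), at(hi_bp)
        if j <= i:
            warnings.append(f"+{k} search window empty; stopping at +{k - 1}")
            break
        peaks.append(int(pos[i + int(np.argmax(d[i:j]))]))
    if any(b <= a for a, b in zip(peaks, peaks[1:])):
        warnings.append("peak positions not strictly increasing")

    bounds = [0] + peaks + [int(pos[-1])]
    degrees = []
    for k, pk in enumerate(peaks, start=1):
        troughs = []
        for lo_bp, hi_bp in ((bounds[k - 1], pk), (pk, bounds[k + 1])):
            i, j = at(lo_bp), at(hi_bp) + 1
            if j <= i:
                continue
            troughs.append(int(pos[i + int(np.argmin(d[i:j]))]))
        p_val = _mean_around(d, at(pk), avg_half)
        t_val = float(np.mean([_mean_around(d, at(t), avg_half) for t in troughs]))
        denom = p_val + t_val
        degrees.append((p_val - t_val) / denom if denom > 0 else 0.0)
    return PositioningReport(peaks, degrees, warnings=warnings)


def estimate_periodicity(profile, min_lag: int = 50, min_corr: float = 0.1) -> float:
    """Nucleosome repeat length from the profile autocorrelation.

    Returns the lag (bp) of the first local maximum of the normalized
    autocorrelation beyond ``min_lag`` whose value exceeds ``min_corr``;
    the significance floor keeps chance wiggles of an aperiodic profile
    from passing as a repeat. Raises ValueError("aperiodic") if none.
    """
    d = profile.density if isinstance(profile, DyadProfile) else np.asarray(profile, float)
    x = d - d.mean()
    n = len(x)
    if float(x @ x) == 0:
        raise ValueError("aperiodic: flat profile")
    # circular autocorrelation: free of the overlap taper that biases the
    # linear estimator's maximum toward smaller lags
    spec = np.abs(np.fft.rfft(x)) ** 2
    ac = np.fft.irfft(spec, n)
    ac = ac / ac[0]
    for lag in range(max(min_lag, 1), n // 2):
        if ac[lag] > ac[lag - 1] and ac[lag] >= ac[lag + 1] and ac[lag] > min_corr:
            return float(lag)
    raise ValueError("aperiodic: no significant autocorrelation maximum")


def dyad_relative_6ma(classified: pd.DataFrame, dyads: pd.DataFrame,
                      max_gap: int = 400) -> pd.DataFrame:
    """Relative position of each 6mA between its flanking nucleosome dyads.

    For a site at pos with consecutive dyads d_i <= pos < d_{i+1}, the
    relative position is (pos - d_i)/(d_{i+1} - d_i) in [0, 1); 0.5 is the
    linker midpoint under regular spacing. Dyad pairs further apart than
    ``max_gap`` bp are treated as gaps and their sites excluded.
    """
    rows = []
    by_chrom = {c: np.unique(g["dyad"].to_numpy()) for c, g in dyads.groupby("chrom", sort=False)}
    for chrom, grp in classified.groupby("chrom", sort=False):
        darr = by_chrom.get(chrom)
        if darr is None or len(darr) < 2:
            logger.info("chromosome %s skipped: fewer than 2 dyads", chrom)
            continue
        pos = grp["pos"].to_numpy()
        frac = grp["frac"].to_numpy()
        idx = np.searchsorted(darr, pos, "right") - 1
        ok = (idx >= 0) & (idx < len(darr) - 1)
        left = darr[np.clip(idx, 0, len(darr) - 2)]
        right = darr[np.clip(idx + 1, 1, len(darr) - 1)]
        ok &= (right - left) <= max_gap
        rel = (pos[ok] - left[ok]) / (right[ok] - left[ok])
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos[ok], "relative": rel,
            "level": bin_levels(frac[ok]),
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "relative", "level"])
    return pd.concat(rows, ignore_index=True)


def compare_positioning(gene_sets: dict[str, set], dyads: pd.DataFrame,
                        genes: list[GeneModel], k_max: int = 5,
                        min_genes: int = 50, **profile_kwargs) -> dict:
    """Composite profile and positioning degrees per gene set.

    Returns per-set PositioningReports plus, when both a ``gain`` and a
    ``loss`` set are present, their degree differences for +1 and for the
    mean of +1..+3.
    """
    by_id = {g.gene_id: g for g in genes}
    reports: dict[str, PositioningReport] = {}
    for name, ids in gene_sets.items():
        subset = [by_id[i] for i in ids if i in by_id]
        if not subset:
            logger.warning("gene set %s: no genes found; skipped", name)
            continue
        if len(subset) < min_genes:
            logger.warning("gene set %s: only %d genes (< %d); degrees may be noisy",
                           name, len(subset), min_genes)
        prof = composite_dyad_profile(dyads, subset, **profile_kwargs)
        reports[name] = positioning_degree(prof, k_max=k_max)
    out: dict = {"reports": reports}
    if "gain" in reports and "loss" in reports:
        g, l = reports["gain"].degrees, reports["loss"].degrees
        if g and l:
            out["delta_plus1"] = g[0] - l[0]
            n = min(3, len(g), len(l))
            out["delta_plus1to3"] = float(np.mean(g[:n]) - np.mean(l[:n]))
    return out
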