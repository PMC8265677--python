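"""Duplex-aware classification of methyladenine calls.

Each filtered call is assigned exactly one class:

* ``symmetric`` — both adenines of its ApT duplex are called (full
  methylation of the dinucleotide on both strands); counted as two
  methylated adenines, one per strand;
* ``asymmetric`` — the call sits in an ApT duplex whose partner adenine is
  absent from the call set (hemimethylation);
* ``non_apt`` — the strand-local 3' neighbour is not T.

Methylation levels are binned L1..L5 in 20% steps, L5 closed at 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import percent, reverse_complement, round1
from .genome_io import Genome

CLASSES = ("symmetric", "asymmetric", "non_apt")
LEVELS = ("L1", "L2", "L3", "L4", "L5")
_LEVEL_EDGES = np.array([0.2, 0.4, 0.6, 0.8])


def bin_level(frac: float) -> str:
    """L1..L5 bin of a methylated fraction: [0,.2), [.2,.4), ... [.8,1]."""
    return bin_levels(np.asarray([frac]))[0]


def bin_levels(frac) -> np.ndarray:
    frac = np.asarray(frac, dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("methylated fraction outside [0, 1]")
    idx = np.digitize(frac, _LEVEL_EDGES, right=False)  # 0.2 -> L2, 1.0 -> L5
    return np.asarray(LEVELS, dtype=object)[idx]


def classify_sites(callset, genome: Genome) -> pd.DataFrame:
    """Assign class, level bin and duplex id to every call.

    Returns the call table with added columns ``cls``, ``level`` and
    ``duplex_pos`` (Watson coordinate of the ApT duplex; -1 for non-ApT).
    Symmetry is evaluated on the given (already filtered) call set: a
    partner adenine lost to the confidence filter leaves the survivor
    asymmetric.
    """
    df = callset.df.reset_index(drop=True).copy()
    cls = np.empty(len(df), dtype=object)
    duplex_pos = np.full(len(df), -1, dtype=np.int64)

    for chrom, idx in df.groupby("chrom", sort=False).groups.items():
        seq = np.frombuffer(genome.sequence(chrom).encode(), dtype=np.uint8)
        sub = df.loc[idx]
        pos = sub["pos"].to_numpy()
        plus = sub["strand"].to_numpy() == "+"
        base = seq[pos]
        want = np.where(plus, ord("A"), ord("T"))
        if (base != want).any():
            bad = pos[base != want][0]
            raise ValueError(
                f"call at {chrom}:{bad} is not an adenine on its strand; "
                "run ingest with a genome to drop such records"
            )
        # strand-local 3' neighbour: seq[pos+1] for Watson, seq[pos-1]=='A' for Crick
        nxt = np.full(len(sub), 0, dtype=np.uint8)
        w_ok = plus & (pos + 1 < len(seq))
        nxt[w_ok] = seq[pos[w_ok] + 1]
        c_ok = ~plus & (pos - 1 >= 0)
        is_apt = np.zeros(len(sub), dtype=bool)
        is_apt[w_ok] = nxt[w_ok] == ord("T")
        is_apt[c_ok] |= seq[pos[c_ok] - 1] == ord("A")

        dpos = np.where(plus, pos, pos - 1)  # duplex Watson coordinate
        called = set(zip(pos.tolist(), np.where(plus, "+", "-").tolist()))
        partner_called = np.fromiter(
            (
                ((p + 1, "-") in called) if pl else ((p - 1, "+") in called)
                for p, pl in zip(pos.tolist(), plus.tolist())
            ),
            dtype=bool,
            count=len(sub),
        )
        c = np.where(
            is_apt, np.where(partner_called, "symmetric", "asymmetric"), "non_apt"
        )
        loc = df.index.get_indexer(idx)
        cls[loc] = c
        duplex_pos[loc] = np.where(is_apt, dpos, -1)

    df["cls"] = cls
    df["level"] = bin_levels(df["frac"].to_numpy())
    df["duplex_pos"] = duplex_pos
    df.attrs["genome_checksum"] = genome.checksum()
    df.attrs["label"] = callset.label
    return df


@dataclass
class CompositionSummary:
    """Class and level-bin composition of a classified call set.

    Counts are methylated adenines (symmetric duplexes contribute both
    members); percentages are of the total and rounded to one decimal,
    half away from zero, as in printed summary tables.
    """

    class_counts: dict[str, int]
    level_counts: dict[str, int]
    density: float | None = None  # 6mA/A over the genome, if computed
    total: int = field(init=False)

    def __post_init__(self) -> None:
        ct = sum(self.class_counts.values())
        lt = sum(self.level_counts.values())
        if self.level_counts and ct != lt:
            raise ValueError(f"class total {ct} != level total {lt}")
        if self.class_counts.get("symmetric", 0) % 2:
            raise ValueError("symmetric adenine count must be even (duplex pairs)")
        self.total = ct

    @classmethod
    def from_counts(cls, symmetric_pairs: int, asymmetric: int, non_apt: int,
                    level_counts: dict[str, int] | None = None,
                    density: float | None = None) -> "CompositionSummary":
        """Build from printed-table style counts (symmetric given as pairs)."""
        return cls(
            {"symmetric": 2 * symmetric_pairs, "asymmetric": asymmetric, "non_apt": non_apt},
            dict(level_counts or {}),
            density,
        )

    @property
    def class_pct(self) -> dict[str, float]:
        return {k: percent(v, self.total) for k, v in self.class_counts.items()}

    @property
    def level_pct(self) -> dict[str, float]:
        return {k: percent(v, self.total) for k, v in self.level_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", self.total, 100.0)]
        rows += [(k, v, self.class_pct[k]) for k, v in self.class_counts.items()]
        rows += [(k, v, self.level_pct[k]) for k, v in self.level_counts.items()]
        return pd.DataFrame(rows, columns=["group", "adenines", "pct"])


def summarize_composition(classified: pd.DataFrame, genome: Genome | None = None) -> CompositionSummary:
    """Adenine counts and percentages per class and level bin (Table-1 style)."""
    if len(classified) == 0:
        raise ValueError("no classified sites to summarize")
    cc = classified["cls"].value_counts().to_dict()
    lc = classified["level"].value_counts().to_dict()
    density = None
    if genome is not None:
        from .genome_io import adenine_count

        density = len(classified) / adenine_count(genome)
    return CompositionSummary(
        {k: int(cc.get(k, 0)) for k in CLASSES},
        {k: int(lc.get(k, 0)) for k in LEVELS},
        density,
    )


def apt_fraction(summary: CompositionSummary) -> tuple[float, float]:
    """(ApT %, non-ApT %) of methylated adenines; ApT = symmetric + asymmetric."""
    non_apt = percent(summary.class_counts.get("non_apt", 0), summary.total)
    return (round1(100.0 - non_apt), non_apt)


def chromosome_density(classified: pd.DataFrame, genome: Genome,
                       bin_size: int = 1000, both_strands: bool = True) -> pd.DataFrame:
    """Per-1-kb 6mA/A density: methylated adenines / adenines in each bin.

    Denominators count strand-resolved adenines (Watson A + Crick A) by
    default, matching strand-resolved calls; ``both_strands=False`` counts
    Watson A only. Bins with zero adenines get NaN density, not 0.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    by_chrom = dict(iter(classified.groupby("chrom", sort=False)))
    for chrom, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n_bins = (len(seq) + bin_size - 1) // bin_size
        is_a = arr == ord("A")
        if both_strands:
            is_a = is_a | (arr == ord("T"))
        bin_idx = np.arange(len(seq)) // bin_size
        a_counts = np.bincount(bin_idx, weights=is_a, minlength=n_bins)
        m_counts = np.zeros(n_bins)
        if chrom in by_chrom:
            pos = by_chrom[chrom]["pos"].to_numpy()
            m_counts = np.bincount(pos // bin_size, minlength=n_bins).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            dens = np.where(a_counts > 0, m_counts / a_counts, np.nan)
        for b in range(n_bins):
            rows.append((chrom, b * bin_size, int(m_counts[b]), int(a_counts[b]), dens[b]))
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "n_6ma", "n_a", "density"])


def per_chromosome_density(classified: pd.DataFrame, genome: Genome,
                           both_strands: bool = True) -> pd.DataFrame:
    """Whole-chromosome 6mA/A, with length, orderable for genome overviews."""
    per_bin = chromosome_density(classified, genome, bin_size=max(genome.lengths.values()),
                                 both_strands=both_strands)
    out = per_bin.groupby("chrom", sort=False).agg(
        n_6ma=("n_6ma", "sum"), n_a=("n_a", "sum")
    )
    out["length"] = pd.Series(genome.lengths)
    out["density"] = out["n_6ma"] / out["n_a"]
    return out.reset_index()


def motif_matrix(classified: pd.DataFrame, genome: Genome, flank: int = 20) -> pd.DataFrame:
    """Position-frequency counts over [-flank, +flank] around each site.

    Crick-strand sites contribute the reverse-complement window so that
    position 0 is always the methylated A read 5'->3'. Windows truncated by
    a chromosome edge are excluded, so every column sums to the number of
    contributing sites.
    """
    if len(classified) == 0:
        raise ValueError("no sites for motif matrix")
    width = 2 * flank + 1
    counts = {b: np.zeros(width, dtype=np.int64) for b in "ACGTN"}
    n_used = 0
    for row in classified.itertuples(index=False):
        seq = genome.sequence(row.chrom)
        lo, hi = row.pos - flank, row.pos + flank + 1
        if lo < 0 or hi > len(seq):
            continue
        window = seq[lo:hi]
        if row.strand == "-":
            window = reverse_complement(window)
        for i, b in enumerate(window):
            counts[b][i] += 1
        n_used += 1
    mat = pd.DataFrame(
        {b: counts[b] for b in "ACGT"}, index=np.arange(-flank, flank + 1)
    ).T
    mat.attrs["n_sites"] = n_used
    return mat
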