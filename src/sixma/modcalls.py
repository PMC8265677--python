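"""Ingest per-adenine base-modification calls, normalize coverage, filter.

A call set is held as a DataFrame with one row per strand-resolved adenine:
``chrom, pos (0-based), strand, coverage, qv, frac``. ``frac`` is the
estimated fraction of DNA molecules methylated at the site, stored in
[0, 1]; percent scales exist only at presentation time. In the polyploid
macronucleus (~45 chromosome copies) this fraction is the per-site
methylation level and varies almost continuously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import Genome, ParseError

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "coverage", "qv", "frac"]


@dataclass
class CallSet:
    """Per-adenine modification calls for one condition (e.g. Veg, S24)."""

    label: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("condition label must be nonempty")
        missing = [c for c in CALL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"call table missing columns {missing}")
        if ((self.df["frac"] < 0) | (self.df["frac"] > 1)).any():
            raise ValueError("frac must lie in [0, 1]")
        dup = self.df.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate (chrom,pos,strand) calls")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mean_raw_coverage(self) -> float:
        if len(self.df) == 0:
            raise ValueError(f"call set {self.label!r} is empty")
        return float(self.df["coverage"].mean())


def _check_reference_adenines(df: pd.DataFrame, genome: Genome) -> pd.Series:
    """Boolean mask of rows whose reference base reads A on the stated strand."""
    ok = np.zeros(len(df), dtype=bool)
    for chrom, idx in df.groupby("chrom", sort=False).groups.items():
        if chrom not in genome:
            raise ParseError(f"call on unknown chromosome {chrom!r}")
        seq = np.frombuffer(genome.sequence(chrom).encode(), dtype=np.uint8)
        sub = df.loc[idx]
        pos = sub["pos"].to_numpy()
        if (pos < 0).any() or (pos >= len(seq)).any():
            raise ParseError(f"call position outside chromosome {chrom}")
        base = seq[pos]
        want = np.where(sub["strand"].to_numpy() == "+", ord("A"), ord("T"))
        ok[df.index.get_indexer(idx)] = base == want
    return pd.Series(ok, index=df.index)


def read_modifications_gff(path, genome: Genome, label: str = "calls",
                           on_missing_frac: str = "error") -> CallSet:
    """Parse an SMRT-Link-style modifications GFF (m6A records).

    Coordinates are 1-based in the file; the score column carries the
    modification Qv; ``coverage`` and ``frac`` (0-1) live in the attribute
    column. Records whose reference base is not A on the stated strand are
    dropped with a logged count. ``on_missing_frac``: "error" or "drop".
    """
    if on_missing_frac not in ("error", "drop"):
        raise ValueError("on_missing_frac must be 'error' or 'drop'")
    rows = []
    n_missing_frac = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start1, _end1, score, strand, _phase, attrs = cols
            if ftype != "m6A":
                continue
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attr = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            if "coverage" not in attr:
                raise ParseError(f"{path}:{lineno}: missing coverage attribute")
            if "frac" not in attr:
                if on_missing_frac == "error":
                    raise ParseError(
                        f"{path}:{lineno}: missing frac attribute "
                        "(methylated fraction drives the amount statistic)"
                    )
                n_missing_frac += 1
                continue
            rows.append(
                (chrom, int(start1) - 1, strand, float(attr["coverage"]),
                 float(score), float(attr["frac"]))
            )
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if len(df):
        ok = _check_reference_adenines(df, genome)
        n_bad = int((~ok).sum())
        if n_bad:
            logger.info("%s: dropped %d calls whose reference base is not A", path, n_bad)
        df = df[ok].reset_index(drop=True)
    if n_missing_frac:
        logger.info("%s: dropped %d records lacking frac", path, n_missing_frac)
    return CallSet(label, df)


def write_modifications_gff(callset: CallSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in callset.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tkinModCall\tm6A\t{row.pos + 1}\t{row.pos + 1}\t"
                f"{row.qv:g}\t{row.strand}\t.\t"
                f"coverage={row.coverage:g};frac={row.frac:.6f}\n"
            )


def read_calls(path, label: str = "calls") -> CallSet:
    """Read the canonical calls TSV (chrom, pos0, strand, coverage, qv, frac)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    df = df.rename(columns={"pos0": "pos"})
    return CallSet(label, df[CALL_COLUMNS])


def write_calls(callset: CallSet, path) -> None:
    out = callset.df[CALL_COLUMNS].rename(columns={"pos": "pos0"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def normalize_coverage(callset: CallSet, target: float = 100.0) -> CallSet:
    """Scale coverages by one global factor so their mean equals ``target``.

    A single scalar (not per-chromosome), taken over calls because only
    called sites carry coverage in the input.
    """
    mean = callset.mean_raw_coverage
    if mean <= 0:
        raise ValueError("mean raw coverage must be positive")
    df = callset.df.copy()
    df["coverage"] = df["coverage"] * (target / mean)
    return CallSet(callset.label, df)


def filter_calls(callset: CallSet, min_qv: float = 30.0, min_cov: float = 25.0) -> CallSet:
    """Confidence filter: keep calls with qv > min_qv AND coverage > min_cov.

    Both cutoffs are strict inequalities; coverage is expected to be
    normalized already.
    """
    df = callset.df
    keep = (df["qv"] > min_qv) & (df["coverage"] > min_cov)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("%s: filter removed %d of %d calls", callset.label, n_drop, len(df))
    return CallSet(callset.label, df[keep].reset_index(drop=True))
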