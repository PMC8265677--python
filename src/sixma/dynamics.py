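"""Cross-condition site matching and transition accounting.

Sites are matched per strand-resolved adenine (chrom, pos, strand); an
adenine absent from a condition's filtered call set is "unmethylated" in
that condition — indistinguishable, by construction, from sub-threshold
methylation. Adenine-level accounting is primary (composition tables count
adenines); the duplex-level view is derived where needed.
"""

from __future__ import annotations

import pandas as pd

from ._util import percent
from .genome_io import Genome

STATES = ("symmetric", "asymmetric", "non_apt", "unmethylated")


def match_conditions(classified_a: pd.DataFrame, classified_b: pd.DataFrame,
                     genome: Genome | None = None) -> pd.DataFrame:
    """Per-adenine duplex state in condition A vs condition B.

    Returns one row per (chrom, pos, strand) present in either classified
    set, with ``state_a`` and ``state_b``. Classified inputs carry the
    checksum of the genome they were classified against; a mismatch (or a
    mismatch with an explicitly supplied genome) is an error.
    """
    sums = {classified_a.attrs.get("genome_checksum"), classified_b.attrs.get("genome_checksum")}
    if genome is not None:
        sums.add(genome.checksum())
    sums.discard(None)
    if len(sums) > 1:
        raise ValueError("condition call sets were classified against different genomes")

    key = ["chrom", "pos", "strand"]
    a = classified_a[key + ["cls"]].rename(columns={"cls": "state_a"})
    b = classified_b[key + ["cls"]].rename(columns={"cls": "state_b"})
    merged = a.merge(b, on=key, how="outer")
    merged["state_a"] = merged["state_a"].fillna("unmethylated")
    merged["state_b"] = merged["state_b"].fillna("unmethylated")
    return merged.sort_values(key).reset_index(drop=True)


def transition_matrix(transitions: pd.DataFrame) -> pd.DataFrame:
    """Adenine counts indexed state_A x state_B, with fixed state order.

    Row sums equal condition-A state counts and column sums condition-B
    state counts over the matched universe (unmethylated-in-both pairs are
    absent from the input, so that cell is structurally zero).
    """
    mat = pd.crosstab(transitions["state_a"], transitions["state_b"])
    mat = mat.reindex(index=STATES, columns=STATES, fill_value=0)
    mat.index.name = "state_a"
    mat.columns.name = "state_b"
    return mat


def transition_fractions(matrix: pd.DataFrame, denominators: pd.Series | dict) -> pd.DataFrame:
    """Each transition count as a percent of an explicit per-row denominator.

    The denominator choice (e.g. condition-A symmetric adenines, or
    condition-B symmetric adenines) is the caller's, made explicit because
    published fractions mix conventions. Percentages to one decimal.
    """
    denominators = pd.Series(denominators)
    out = matrix.astype(float).copy()
    for state in matrix.index:
        if state not in denominators or denominators[state] == 0:
            raise ValueError(f"no nonzero denominator for state {state!r}")
        out.loc[state] = [percent(v, denominators[state]) for v in matrix.loc[state]]
    return out


def gene_l5_asym_change(classified_a: pd.DataFrame, classified_b: pd.DataFrame,
                        genes, window: int = 1000) -> dict:
    """Genes gaining or losing highly methylated (L5) asymmetric 6mA.

    Counts L5 asymmetric adenines in the strand-aware [TSS, TSS+window)
    interval of each gene in both conditions. ``gain``: count_B > count_A;
    ``loss``: count_B < count_A; ties belong to neither.
    """
    if window <= 0:
        raise ValueError("window must be positive")

    def counts(classified: pd.DataFrame) -> dict[str, int]:
        hot = classified[(classified["cls"] == "asymmetric") & (classified["level"] == "L5")]
        by_chrom = {c: g["pos"].to_numpy() for c, g in hot.groupby("chrom", sort=False)}
        out = {}
        for gene in genes:
            pos = by_chrom.get(gene.chrom)
            if pos is None:
                out[gene.gene_id] = 0
                continue
            if gene.strand == "+":
                lo, hi = gene.tss, gene.tss + window
            else:
                lo, hi = gene.tss - window + 1, gene.tss + 1
            out[gene.gene_id] = int(((pos >= lo) & (pos < hi)).sum())
        return out

    ca, cb = counts(classified_a), counts(classified_b)
    table = pd.DataFrame(
        {"count_a": pd.Series(ca), "count_b": pd.Series(cb)}
    ).rename_axis("gene_id")
    return {
        "gain": {g for g in ca if cb[g] > ca[g]},
        "loss": {g for g in ca if cb[g] < ca[g]},
        "counts": table,
    }


def _duplex_states(transitions: pd.DataFrame) -> pd.DataFrame:
    """Duplex-level state pairs for adenines lying in ApT duplexes.

    A duplex's state in a condition is symmetric iff both adenines are
    called, asymmetric iff exactly one, unmethylated iff neither.
    """
    t = transitions[transitions["state_a"].isin(("symmetric", "asymmetric"))
                    | transitions["state_b"].isin(("symmetric", "asymmetric"))].copy()
    t["watson_pos"] = t["pos"].where(t["strand"] == "+", t["pos"] - 1)

    def duplex_state(states: pd.Series) -> str:
        called = (states != "unmethylated") & (states != "non_apt")
        n = int(called.sum())
        return "symmetric" if n == 2 else ("asymmetric" if n == 1 else "unmethylated")

    grp = t.groupby(["chrom", "watson_pos"])
    out = grp.agg(
        state_a=("state_a", duplex_state), state_b=("state_b", duplex_state)
    )
    return out.reset_index()


def select_conversion_gatc_sites(transitions: pd.DataFrame, genome: Genome,
                                 kind: str = "conversion") -> list[tuple[str, int]]:
    """ApT duplexes inside GATC usable for DpnI/DpnII qPCR validation.

    ``conversion``: symmetric in condition A, fully unmethylated in B.
    ``retain``: symmetric in both. The duplex must form the AT core of a
    Watson-strand GATC tetramer (the DpnI/DpnII recognition site).
    Returns (chrom, watson_pos) of the duplex's Watson adenine.
    """
    if kind not in ("conversion", "retain"):
        raise ValueError("kind must be 'conversion' or 'retain'")
    want_b = "unmethylated" if kind == "conversion" else "symmetric"
    duplexes = _duplex_states(transitions)
    sel = duplexes[(duplexes["state_a"] == "symmetric") & (duplexes["state_b"] == want_b)]
    out = []
    for row in sel.itertuples(index=False):
        seq = genome.sequence(row.chrom)
        p = int(row.watson_pos)
        if p - 1 >= 0 and p + 3 <= len(seq) and seq[p - 1 : p + 3] == "GATC":
            out.append((row.chrom, p))
    return out
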