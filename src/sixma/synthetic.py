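"""Synthetic data generator for every input the pipeline consumes.

The generator emulates the statistical structure the analysis assumes:

* an AT-rich multi-chromosome genome (default AT content 0.75) with genes
  tiled on both strands;
* duplex 6mA calls in two conditions, with class-conditional methylation
  level mixtures (symmetric levels concentrated high, asymmetric bimodal
  and shifting high in the starved condition) and a duplex transition
  kernel between conditions;
* phased nucleosome dyad arrays downstream of TSSs with optional linker
  enrichment of 6mA placement;
* expression counts whose log2 fold changes are partially coupled to the
  true 6mA amount change near the TSS;
* Ct quadruplets for conversion/retain qPCR validation sites.

One global seed fully determines all outputs; every generator draws from
its own named substream so adding one never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._util import substream
from .genome_io import GeneModel, Genome, apt_watson_positions
from .modcalls import CALL_COLUMNS, CallSet

DUPLEX_STATES = ("symmetric", "asymmetric", "unmethylated")

# Per-duplex/per-adenine methylation rates reproducing the vegetative
# composition (class split ~61/27/12 of methylated adenines, overall
# density ~0.5% 6mA/A) on an AT-0.75 genome; derivation in the methods
# note. The kernel rows give the duplex state in the starved condition
# given the vegetative state, emulating the observed directionality
# (symmetric loss to asymmetric/unmethylated, little re-methylation).
DEFAULT_KERNEL = np.array([
    [0.40, 0.23, 0.37],   # symmetric ->
    [0.05, 0.45, 0.50],   # asymmetric ->
    [0.001, 0.004, 0.995],  # unmethylated ->
])

# Beta-mixture level models per class: list of (weight, alpha, beta).
DEFAULT_LEVELS_A = {
    "symmetric": [(1.0, 8.0, 2.0)],
    "asymmetric": [(0.55, 2.0, 5.0), (0.45, 8.0, 2.0)],
    "non_apt": [(1.0, 3.0, 3.0)],
}
DEFAULT_LEVELS_B = {
    "symmetric": [(1.0, 8.0, 2.0)],
    "asymmetric": [(0.25, 2.0, 5.0), (0.75, 9.0, 1.5)],  # shifted high when starved
    "non_apt": [(1.0, 3.0, 3.0)],
}


@dataclass
class SimConfig:
    """All knobs of the simulator; the defaults are the study conditions."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (200_000, 150_000, 100_000)
    at_content: float = 0.75
    gene_length: int = 2_000
    gene_spacing: int = 1_000

    # methylation placement (condition A / vegetative)
    p_sym: float = 0.0088      # per ApT duplex
    p_asym: float = 0.0077     # per ApT duplex
    p_nonapt: float = 0.00105  # per non-ApT strand-resolved adenine
    kernel: np.ndarray = field(default_factory=lambda: DEFAULT_KERNEL.copy())
    nonapt_retain: float = 0.33
    levels_a: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_LEVELS_A.items()})
    levels_b: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_LEVELS_B.items()})
    copy_number: int | None = None  # if set, levels become k/n with k ~ Binomial(n, level)

    # per-call sequencing model
    coverage_mean: float = 103.0
    coverage_disp: float = 10.0  # negative-binomial shape
    qv_mean: float = 42.0
    qv_sd: float = 8.0

    # nucleosomes
    spacing: int = 200
    first_dyad: int = 100      # +1 dyad offset downstream of TSS
    n_nucleosomes: int = 6
    dyad_jitter: float = 20.0  # sd of fragment midpoints around the true dyad
    frag_len_mean: float = 147.0
    frag_len_sd: float = 15.0
    frags_per_dyad: float = 20.0
    bg_fragment_frac: float = 0.10
    linker_enrichment: float = 1.0  # weight multiplier for linker 6mA placement

    # expression coupling
    coupling_rho: float = 0.3
    expression_noise_sd: float = 1.0
    baseline_log_mean: float = np.log(500.0)
    baseline_log_sd: float = 1.0
    counts_disp: float = 5.0

    # qPCR
    ct_baseline: float = 18.0
    ct_digest_shift: float = 5.0
    ct_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.shape != (3, 3):
            raise ValueError("kernel must be 3x3 over (symmetric, asymmetric, unmethylated)")
        if not np.allclose(self.kernel.sum(axis=1), 1.0):
            raise ValueError("kernel rows must sum to 1")
        if ((self.kernel < 0) | (self.kernel > 1)).any():
            raise ValueError("kernel entries must be probabilities")
        if self.p_sym + self.p_asym > 1:
            raise ValueError("p_sym + p_asym must not exceed 1")
        for p in (self.p_sym, self.p_asym, self.p_nonapt, self.nonapt_retain):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.at_content <= 1:
            raise ValueError("at_content must lie in [0, 1]")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class TruthTable:
    """Ground truth written alongside the simulated files."""

    duplexes: pd.DataFrame  # chrom, watson_pos, state_a, state_b, asym strand per condition
    nonapt: pd.DataFrame    # chrom, pos, strand, in_a, in_b
    genes: pd.DataFrame | None = None  # gene_id, amount_a, amount_b, log2fc (filled later)


def simulate_genome(config: SimConfig) -> tuple[Genome, list[GeneModel]]:
    """I.i.d.-base genome at the configured AT content, with tiled genes."""
    rng = substream(config.seed, "genome")
    at, gc = config.at_content, 1.0 - config.at_content
    probs = [at / 2, at / 2, gc / 2, gc / 2]
    bases = np.array(list("ATCG"), dtype="U1")
    chroms: dict[str, str] = {}
    genes: list[GeneModel] = []
    for ci, length in enumerate(config.chrom_lengths):
        name = f"chr{ci + 1}"
        if length < 2_000:
            raise ValueError(f"{name}: chromosomes shorter than 2 kb cannot hold genes")
        seq = "".join(bases[rng.choice(4, size=length, p=probs)])
        chroms[name] = seq
        pos, gi = 1_000, 0
        while pos + config.gene_length + 1_000 <= length:
            strand = "+" if gi % 2 == 0 else "-"
            genes.append(GeneModel(f"{name}_g{gi}", name, pos, pos + config.gene_length, strand))
            pos += config.gene_length + config.gene_spacing
            gi += 1
    return Genome(chroms), genes


def _draw_levels(rng: np.random.Generator, mixture, n: int,
                 copy_number: int | None) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    weights = np.array([w for w, _, _ in mixture], dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(mixture), size=n, p=weights)
    a = np.array([a for _, a, _ in mixture])[comp]
    b = np.array([b for _, _, b in mixture])[comp]
    levels = rng.beta(a, b)
    if copy_number:
        levels = rng.binomial(copy_number, levels) / copy_number
    return levels


def _linker_weights(positions: np.ndarray, dyads: np.ndarray, config: SimConfig) -> np.ndarray:
    """Placement weight per position: ``linker_enrichment`` when the position
    is further than ~half a nucleosome (73 bp) from every dyad, else 1."""
    w = np.ones(len(positions))
    if config.linker_enrichment == 1.0 or len(dyads) == 0:
        return w
    d = np.sort(dyads)
    idx = np.searchsorted(d, positions)
    left = d[np.clip(idx - 1, 0, len(d) - 1)]
    right = d[np.clip(idx, 0, len(d) - 1)]
    dist = np.minimum(np.abs(positions - left), np.abs(positions - right))
    w[dist > 73] = config.linker_enrichment
    return w


def simulate_callsets(config: SimConfig, genome: Genome,
                      dyad_truth: pd.DataFrame | None = None
                      ) -> tuple[CallSet, CallSet, TruthTable]:
    """Two-condition duplex call sets plus ground truth.

    Condition-A duplex states are drawn from (p_sym, p_asym, rest
    unmethylated), optionally re-weighted toward linker DNA when a dyad
    truth table and ``linker_enrichment`` > 1 are given; condition-B
    states follow the transition kernel. Non-ApT methylation is placed
    independently and retained in B with probability ``nonapt_retain``.
    """
    rng = substream(config.seed, "callsets")
    duplex_rows, nonapt_rows = [], []
    calls = {"A": [], "B": []}

    dyads_by_chrom: dict[str, np.ndarray] = {}
    if dyad_truth is not None:
        dyads_by_chrom = {c: g["dyad"].to_numpy() for c, g in dyad_truth.groupby("chrom")}

    for chrom, seq in genome.chromosomes.items():
        wpos = apt_watson_positions(seq)
        if len(wpos):
            w = _linker_weights(wpos, dyads_by_chrom.get(chrom, np.empty(0)), config)
            w = w / w.mean()
            p_sym = np.clip(config.p_sym * w, 0, 1)
            p_asym = np.clip(config.p_asym * w, 0, 1 - p_sym)
            u = rng.random(len(wpos))
            state_a = np.where(u < p_sym, 0, np.where(u < p_sym + p_asym, 1, 2))
            state_b = np.empty(len(wpos), dtype=int)
            for s in range(3):
                mask = state_a == s
                state_b[mask] = rng.choice(3, size=int(mask.sum()), p=config.kernel[s])
            asym_strand_a = rng.choice(["+", "-"], size=len(wpos))
            keep_strand = state_a == state_b  # asym->asym keeps its strand
            asym_strand_b = np.where(keep_strand, asym_strand_a,
                                     rng.choice(["+", "-"], size=len(wpos)))
            for i in range(len(wpos)):
                sa, sb = DUPLEX_STATES[state_a[i]], DUPLEX_STATES[state_b[i]]
                if sa == "unmethylated" and sb == "unmethylated":
                    continue
                duplex_rows.append((chrom, int(wpos[i]), sa, sb,
                                    asym_strand_a[i], asym_strand_b[i]))
        # strand-resolved non-ApT adenines: Watson A not followed by T,
        # Crick A (Watson T) not preceded by A
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        wa = np.where(arr == ord("A"))[0]
        wa = wa[(wa + 1 >= len(arr)) | (arr[np.minimum(wa + 1, len(arr) - 1)] != ord("T"))]
        ct = np.where(arr == ord("T"))[0]
        ct = ct[(ct - 1 < 0) | (arr[np.maximum(ct - 1, 0)] != ord("A"))]
        for pos_arr, strand in ((wa, "+"), (ct, "-")):
            hit = pos_arr[rng.random(len(pos_arr)) < config.p_nonapt]
            in_b = rng.random(len(hit)) < config.nonapt_retain
            for p, rb in zip(hit.tolist(), in_b.tolist()):
                nonapt_rows.append((chrom, p, strand, True, rb))

    duplexes = pd.DataFrame(duplex_rows, columns=[
        "chrom", "watson_pos", "state_a", "state_b", "asym_strand_a", "asym_strand_b"])
    nonapt = pd.DataFrame(nonapt_rows, columns=["chrom", "pos", "strand", "in_a", "in_b"])

    def emit(cond: str) -> None:
        state_col, strand_col = f"state_{cond.lower()}", f"asym_strand_{cond.lower()}"
        for row in duplexes.itertuples(index=False):
            state = getattr(row, state_col)
            if state == "symmetric":
                adenines = [(row.watson_pos, "+"), (row.watson_pos + 1, "-")]
            elif state == "asymmetric":
                s = getattr(row, strand_col)
                adenines = [(row.watson_pos if s == "+" else row.watson_pos + 1, s)]
            else:
                continue
            mixture = (config.levels_a if cond == "A" else config.levels_b)["symmetric" if state == "symmetric" else "asymmetric"]
            levels = _draw_levels(rng, mixture, len(adenines), config.copy_number)
            for (p, s), lv in zip(adenines, levels):
                calls[cond].append((row.chrom, p, s, lv))
        flag = "in_a" if cond == "A" else "in_b"
        sub = nonapt[nonapt[flag]]
        levels = _draw_levels(
            rng, (config.levels_a if cond == "A" else config.levels_b)["non_apt"],
            len(sub), config.copy_number)
        for row, lv in zip(sub.itertuples(index=False), levels):
            calls[cond].append((row.chrom, row.pos, row.strand, lv))

    emit("A")
    emit("B")

    def to_callset(rows: list, label: str) -> CallSet:
        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "frac"])
        n = len(df)
        p = config.coverage_disp / (config.coverage_disp + config.coverage_mean)
        df["coverage"] = rng.negative_binomial(config.coverage_disp, p, size=n).astype(float)
        df["qv"] = np.clip(rng.normal(config.qv_mean, config.qv_sd, size=n), 1.0, None)
        return CallSet(label, df[CALL_COLUMNS].sort_values(["chrom", "pos", "strand"]).reset_index(drop=True))

    return to_callset(calls["A"], "Veg"), to_callset(calls["B"], "S24"), TruthTable(duplexes, nonapt)


def simulate_mnase(config: SimConfig, genome: Genome, genes: list[GeneModel]
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phased nucleosome fragments downstream of each TSS, plus dyad truth.

    True dyads sit at TSS + first_dyad + spacing*k in the gene's reading
    direction; fragment midpoints scatter around them with sd
    ``dyad_jitter`` and lengths ~ N(frag_len_mean, frag_len_sd). A
    ``bg_fragment_frac`` fraction of fragments is uniform background.
    """
    rng = substream(config.seed, "mnase")
    frag_rows, dyad_rows = [], []
    for gene in genes:
        sign = 1 if gene.strand == "+" else -1
        for k in range(config.n_nucleosomes):
            center = gene.tss + sign * (config.first_dyad + config.spacing * k)
            if not 0 <= center < genome.lengths[gene.chrom]:
                continue
            dyad_rows.append((gene.chrom, int(center), gene.gene_id, k + 1))
            n = rng.poisson(config.frags_per_dyad)
            mids = np.rint(rng.normal(center, config.dyad_jitter, size=n)).astype(int)
            lens = np.clip(np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, size=n)), 90, 210).astype(int)
            starts = np.clip(mids - lens // 2, 0, None)
            for st, ln in zip(starts.tolist(), lens.tolist()):
                en = min(st + ln, genome.lengths[gene.chrom])
                if en - st >= 90:
                    frag_rows.append((gene.chrom, st, en))
    n_sig = len(frag_rows)
    n_bg = int(n_sig * config.bg_fragment_frac / max(1e-12, 1 - config.bg_fragment_frac))
    names = list(genome.chromosomes)
    lengths = np.array([genome.lengths[n] for n in names], dtype=float)
    if n_bg and names:
        which = rng.choice(len(names), size=n_bg, p=lengths / lengths.sum())
        lens = np.clip(np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, size=n_bg)), 90, 210).astype(int)
        for ci, ln in zip(which.tolist(), lens.tolist()):
            st = int(rng.integers(0, max(1, int(lengths[ci]) - ln)))
            frag_rows.append((names[ci], st, st + ln))
    fragments = pd.DataFrame(frag_rows, columns=["chrom", "start", "end"])
    dyad_truth = pd.DataFrame(dyad_rows, columns=["chrom", "dyad", "gene_id", "k"])
    return fragments, dyad_truth


def coupling_coefficient(rho: float, noise_sd: float) -> float:
    """Slope beta giving population correlation rho between a standardized
    signal and beta*signal + N(0, noise_sd^2)."""
    if not -1 < rho < 1:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    return rho * noise_sd / np.sqrt(1.0 - rho * rho)


def simulate_expression(config: SimConfig, amount_change: pd.Series) -> pd.DataFrame:
    """Expression table whose log2FC is partially coupled to 6mA change.

    log2fc = beta * z + eps with z the standardized true amount change,
    beta set from ``coupling_rho``, eps ~ N(0, expression_noise_sd). Raw
    counts are negative-binomial around a log-normal baseline consistent
    with the fold change; padj comes from a sign-randomization null with
    Benjamini-Hochberg adjustment.
    """
    rng = substream(config.seed, "expression")
    x = amount_change.to_numpy(dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("no genes to simulate expression for")
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
    beta = coupling_coefficient(config.coupling_rho, config.expression_noise_sd)
    lfc = beta * z + rng.normal(0.0, config.expression_noise_sd, size=n)

    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    disp = config.counts_disp

    def nb(mean: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(disp, disp / (disp + mean)).astype(int)

    counts_veg = nb(base)
    counts_s24 = nb(base * np.power(2.0, lfc))

    centered = lfc - np.median(lfc)
    null = rng.choice(centered, size=5 * n, replace=True) * rng.choice([-1.0, 1.0], size=5 * n)
    p = (1.0 + (np.abs(null)[None, :] >= np.abs(centered)[:, None]).sum(axis=1)) / (5 * n + 1)
    padj = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame({
        "gene_id": amount_change.index,
        "counts_veg": counts_veg,
        "counts_s24": counts_s24,
        "log2fc": lfc,
        "padj": padj,
        "fpkm_flag": (counts_veg + counts_s24) > 10,
    })


def simulate_ct(config: SimConfig, conversion_sites: list[str],
                retain_sites: list[str]) -> pd.DataFrame:
    """Ct quadruplets per site and condition for DpnI/DpnII validation.

    A methylated (symmetric) site template is cut by DpnI, delaying its
    amplification by ``ct_digest_shift`` cycles; an unmethylated site is
    cut by DpnII. Conversion sites are methylated in Veg and unmethylated
    in S24; retain sites are methylated in both. Gaussian noise with sd
    ``ct_noise_sd`` is added to every Ct.
    """
    rng = substream(config.seed, "ct")
    rows = []
    for site, kind in [(s, "conversion") for s in conversion_sites] + [
            (s, "retain") for s in retain_sites]:
        for cond in ("Veg", "S24"):
            methylated = kind == "retain" or cond == "Veg"
            und = config.ct_baseline
            dpni = und + (config.ct_digest_shift if methylated else 0.0)
            dpnii = und + (0.0 if methylated else config.ct_digest_shift)
            noise = rng.normal(0.0, config.ct_noise_sd, size=3)
            rows.append((site, cond, dpni + noise[0], dpnii + noise[1], und + noise[2]))
    return pd.DataFrame(rows, columns=["site", "condition", "ct_dpni", "ct_dpnii", "ct_undigested"])
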