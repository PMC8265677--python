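"""Methylation-sensitive restriction qPCR arithmetic (DpnI/DpnII).

DpnI cuts methylated GATC and DpnII cuts unmethylated GATC, so the Ct
difference between the two digests reads out the methylation status of a
site: dCt_DpnI = Ct_DpnI - Ct_undigested, dCt_DpnII = Ct_DpnII -
Ct_undigested, ddCt = dCt_DpnI - dCt_DpnII (the undigested control cancels
algebraically), and the cross-condition change dddCt = ddCt_Veg -
ddCt_S24. A site symmetric in vegetative cells but unmethylated after
starvation ("conversion") gives dddCt > 0; a site symmetric in both
("retain") gives dddCt near 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

CT_COLUMNS = ["site", "condition", "ct_dpni", "ct_dpnii", "ct_undigested"]


@dataclass(frozen=True)
class CtRecord:
    site: str
    condition: str
    ct_dpni: float
    ct_dpnii: float
    ct_undigested: float

    def __post_init__(self) -> None:
        for name in ("ct_dpni", "ct_dpnii", "ct_undigested"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"site {self.site} ({self.condition}): missing/non-finite {name}")


def read_ct_csv(path) -> list[CtRecord]:
    """Ct CSV with columns site, condition, ct_dpni, ct_dpnii, ct_undigested."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    return [
        CtRecord(str(r.site), str(r.condition), float(r.ct_dpni),
                 float(r.ct_dpnii), float(r.ct_undigested))
        for r in df.itertuples(index=False)
    ]


def ddct(record: CtRecord) -> float:
    """ddCt = (Ct_DpnI - Ct_und) - (Ct_DpnII - Ct_und) = Ct_DpnI - Ct_DpnII."""
    return (record.ct_dpni - record.ct_undigested) - (record.ct_dpnii - record.ct_undigested)


def dddct(record_veg: CtRecord, record_s24: CtRecord) -> float:
    """Methylation-status change dddCt = ddCt_Veg - ddCt_S24 for one site."""
    if record_veg.site != record_s24.site:
        raise ValueError(f"site mismatch: {record_veg.site!r} vs {record_s24.site!r}")
    return ddct(record_veg) - ddct(record_s24)


def raw_ct_difference(record_veg: CtRecord, record_s24: CtRecord) -> float:
    """Auxiliary simple Veg - S24 difference of ddCt-free DpnI Cts.

    Some summaries report a plain Ct difference between conditions; the
    dddCt statistic above is the primary readout.
    """
    if record_veg.site != record_s24.site:
        raise ValueError(f"site mismatch: {record_veg.site!r} vs {record_s24.site!r}")
    return record_veg.ct_dpni - record_s24.ct_dpni


def qpcr_report(records: list[CtRecord], retain_threshold: float = 1.0) -> pd.DataFrame:
    """Per-site ddCt by condition, dddCt, and a conversion/retain call.

    |dddCt| < ``retain_threshold`` cycles reads "retain"; above it the sign
    decides "conversion" (Veg methylated, S24 not) or "reverse".
    """
    by_site: dict[str, dict[str, CtRecord]] = {}
    for rec in records:
        by_site.setdefault(rec.site, {})[rec.condition] = rec
    rows = []
    for site, conds in sorted(by_site.items()):
        if "Veg" not in conds or "S24" not in conds:
            raise ValueError(f"site {site!r}: need both Veg and S24 records")
        d_veg, d_s24 = ddct(conds["Veg"]), ddct(conds["S24"])
        d3 = d_veg - d_s24
        if abs(d3) < retain_threshold:
            call = "retain"
        else:
            call = "conversion" if d3 > 0 else "reverse"
        rows.append((site, d_veg, d_s24, d3, call))
    return pd.DataFrame(rows, columns=["site", "ddct_veg", "ddct_s24", "dddct", "call"])
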