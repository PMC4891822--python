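"""Stem-loop qRT-PCR relative expression and RNA-seq concordance.

Expression is summarised as dCt = Ct_miRNA - Ct_U6 per condition
(replicates are averaged on the Ct scale before differencing), ddCt is the
treatment-minus-control difference, and the qPCR direction is
sign(-ddCt) — a lower Ct means higher abundance. Concordance with RNA-seq
is the percentage of miRNAs whose qPCR direction matches the sign of the
sequencing log2 fold change; zero directions are excluded from the
denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


def delta_ct(ct_mirna, ct_u6) -> float:
    """dCt = mean(Ct_miRNA) - mean(Ct_U6); scalars or replicate iterables."""
    m = _mean(ct_mirna)
    u = _mean(ct_u6)
    if not (math.isfinite(m) and math.isfinite(u)):
        raise ValueError("Ct values must be finite")
    return m - u


def _mean(v) -> float:
    if hasattr(v, "__iter__"):
        v = list(v)
        if not v:
            raise ValueError("missing Ct replicates")
        return sum(float(x) for x in v) / len(v)
    return float(v)


@dataclass
class QpcrRecord:
    mirna: str
    delta_ct_control: float
    delta_ct_treatment: float

    @property
    def ddct(self) -> float:
        return self.delta_ct_treatment - self.delta_ct_control

    @property
    def direction(self) -> int:
        d = -self.ddct
        return 0 if d == 0 else (1 if d > 0 else -1)


def records_from_table(df: pd.DataFrame) -> list[QpcrRecord]:
    """Build per-miRNA records from a long Ct table.

    Expected columns: mirna, condition (control/treatment), replicate,
    ct_target, ct_u6.
    """
    required = {"mirna", "condition", "ct_target", "ct_u6"}
    if missing := required - set(df.columns):
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct_target"] <= 0).any() or (df["ct_u6"] <= 0).any():
        raise ValueError("Ct values must be positive")
    out = []
    for mid, grp in df.groupby("mirna", sort=True):
        dcts = {}
        for cond in ("control", "treatment"):
            sub = grp[grp["condition"] == cond]
            if sub.empty:
                raise ValueError(f"{mid}: missing {cond} assay")
            dcts[cond] = delta_ct(sub["ct_target"], sub["ct_u6"])
        out.append(QpcrRecord(str(mid), dcts["control"], dcts["treatment"]))
    return out


def concordance_rate(qpcr_directions: dict[str, int], rnaseq_directions: dict[str, int]) -> float:
    """Percent of miRNAs whose qPCR and RNA-seq directions agree.

    Only miRNAs present in both inputs with nonzero directions are
    compared; the rate is reported to two decimals.
    """
    shared = [
        m
        for m in qpcr_directions
        if m in rnaseq_directions and qpcr_directions[m] != 0 and rnaseq_directions[m] != 0
    ]
    if not shared:
        raise ValueError("no comparable miRNAs between qPCR and RNA-seq")
    agree = sum(1 for m in shared if qpcr_directions[m] == rnaseq_directions[m])
    return round(100.0 * agree / len(shared), 2)


def concordance_table(records, log2fcs: dict[str, float]) -> pd.DataFrame:
    """Per-miRNA dCt/ddCt/direction table joined with RNA-seq directions."""
    rows = []
    for r in records:
        lfc = log2fcs.get(r.mirna)
        rna_dir = None if lfc is None else (0 if lfc == 0 else (1 if lfc > 0 else -1))
        rows.append(
            {
                "mirna": r.mirna,
                "delta_ct_control": round(r.delta_ct_control, 4),
                "delta_ct_treatment": round(r.delta_ct_treatment, 4),
                "ddct": round(r.ddct, 4),
                "qpcr_direction": r.direction,
                "rnaseq_log2fc": lfc,
                "rnaseq_direction": rna_dir,
                "agree": (rna_dir is not None and r.direction != 0 and rna_dir == r.direction),
            }
        )
    return pd.DataFrame(rows)
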