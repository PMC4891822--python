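"""TPM normalisation, the Audic-Claverie exact count test, and the
five-way regulation classification.

For a tag with ``x`` reads out of ``N1`` in the control library and ``y``
out of ``N2`` in the treatment library, the Audic-Claverie conditional
point mass is

    p(y|x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is the negative-binomial pmf NB(y; x+1, N1/(N1+N2)); it is evaluated
here in log space via log-gamma. The default p-value is the doubled
smaller tail, min(1, 2*min(P[Y<=y], P[Y>=y])); one-sided alternatives are
available. p-values are always computed from raw counts, never from the
0.01-substituted TPM values, which affect only log2FC and display.

Classification tiers: "significant" requires |log2FC| >= 1 AND p < 0.05;
"slight" requires 0.25 <= |log2FC| < 1 (no p-value condition); everything
else is "unobvious".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

CATEGORIES = [
    "significantly_up",
    "significantly_down",
    "slightly_up",
    "slightly_down",
    "unobvious",
]


@dataclass
class Thresholds:
    min_tpm: float = 2.0
    strong_lfc: float = 1.0
    weak_lfc: float = 0.25
    alpha: float = 0.05
    zero_substitute: float = 0.01

    def __post_init__(self):
        if not 0 < self.weak_lfc < self.strong_lfc:
            raise ValueError("need 0 < weak_lfc < strong_lfc")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class DiffExprPair:
    x: int
    y: int
    N1: int
    N2: int

    def __post_init__(self):
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError("library totals must be positive")
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be non-negative")
        if self.x > self.N1 or self.y > self.N2:
            raise ValueError("count exceeds library total")


def tpm_normalize(count: float, total_clean_reads: int) -> float:
    """count / library total * 1e6. Zero stays zero here."""
    if count < 0:
        raise ValueError("negative count")
    if total_clean_reads <= 0:
        raise ValueError("library total must be positive")
    return count / total_clean_reads * 1_000_000.0


def substitute_zero(tpm: float, zero_substitute: float = 0.01) -> float:
    """Replace an exactly-zero expression by the zero substitute."""
    if tpm < 0:
        raise ValueError("negative TPM")
    return zero_substitute if tpm == 0 else tpm


def audic_log_pmf(y, x: int, N1: int, N2: int):
    """log p(y|x), vectorised over y."""
    y = np.asarray(y, dtype=np.float64)
    r = N2 / N1
    return (
        y * math.log(r)
        + gammaln(x + y + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y + 1.0)
        - (x + y + 1.0) * math.log1p(r)
    )


def audic_point_mass(y: int, x: int, N1: int, N2: int) -> float:
    """The conditional probability p(y|x) itself."""
    return float(np.exp(audic_log_pmf(y, x, N1, N2)))


def audic_pvalue(pair: DiffExprPair, alternative: str = "two-sided") -> float:
    """Audic-Claverie exact p-value for a two-library count pair.

    ``alternative``: "two-sided" (doubled smaller tail, default), "greater"
    (P[Y >= y]) or "less" (P[Y <= y]).
    """
    x, y, N1, N2 = pair.x, pair.y, pair.N1, pair.N2
    ks = np.arange(0, y + 1)
    log_cdf = logsumexp(audic_log_pmf(ks, x, N1, N2))
    lower = min(1.0, float(np.exp(log_cdf)))
    if y == 0:
        upper = 1.0
    else:
        log_cdf_excl = logsumexp(audic_log_pmf(ks[:-1], x, N1, N2))
        upper = max(0.0, 1.0 - float(np.exp(log_cdf_excl)))
        if upper < 1e-8:
            # complement cancels; sum the tail directly until it converges
            logs = []
            k0 = y
            while True:
                chunk = np.arange(k0, k0 + 512)
                lp = audic_log_pmf(chunk, x, N1, N2)
                logs.append(lp)
                if lp[-1] < lp[0] - 50.0 or lp[-1] < -745.0:
                    break
                k0 += 512
            upper = float(np.exp(logsumexp(np.concatenate(logs))))
    if alternative == "less":
        return lower
    if alternative == "greater":
        return upper
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(lower, upper))
    raise ValueError(f"unknown alternative {alternative!r}")


def audic_point_mass_exact(y: int, x: int, N1: int, N2: int):
    """Exact rational evaluation of the point mass (oracle; small counts)."""
    from fractions import Fraction

    r = Fraction(N2, N1)
    val = r**y * Fraction(math.factorial(x + y), math.factorial(x) * math.factorial(y))
    return val / (1 + r) ** (x + y + 1)


@dataclass
class ExpressionProfile:
    mirna: str
    count_c: int
    count_t: int
    tpm_c: float
    tpm_t: float
    log2fc: float
    p_value: float
    category: str
    exclusive_flag: str  # control_only | treatment_only | shared


def classify(
    mirna: str,
    count_c: int,
    count_t: int,
    N1: int,
    N2: int,
    thresholds: Thresholds | None = None,
    alternative: str = "two-sided",
) -> ExpressionProfile:
    """Build the full expression profile for one miRNA."""
    th = thresholds or Thresholds()
    tpm_c = substitute_zero(tpm_normalize(count_c, N1), th.zero_substitute)
    tpm_t = substitute_zero(tpm_normalize(count_t, N2), th.zero_substitute)
    lfc = math.log2(tpm_t / tpm_c)
    p = audic_pvalue(DiffExprPair(count_c, count_t, N1, N2), alternative)
    if abs(lfc) >= th.strong_lfc and p < th.alpha:
        category = "significantly_up" if lfc > 0 else "significantly_down"
    elif th.weak_lfc <= abs(lfc) < th.strong_lfc:
        category = "slightly_up" if lfc > 0 else "slightly_down"
    else:
        category = "unobvious"
    if count_c > 0 and count_t == 0:
        flag = "control_only"
    elif count_t > 0 and count_c == 0:
        flag = "treatment_only"
    else:
        flag = "shared"
    return ExpressionProfile(mirna, count_c, count_t, tpm_c, tpm_t, lfc, p, category, flag)


def filter_low_abundance(profiles, min_tpm: float = 2.0):
    """Keep miRNAs whose TPM reaches ``min_tpm`` in at least one library
    (boundary inclusive)."""
    return [p for p in profiles if max(p.tpm_c, p.tpm_t) >= min_tpm]


def profile_table(
    counts: dict[str, tuple[int, int]],
    N1: int,
    N2: int,
    thresholds: Thresholds | None = None,
    alternative: str = "two-sided",
    bh_column: bool = False,
) -> pd.DataFrame:
    """Profile every miRNA and return the expression table.

    ``counts`` maps miRNA id to (count_c, count_t). The returned frame has
    one row per miRNA with TPM, log2FC, Audic p-value, regulation category
    and exclusivity flag; an optional Benjamini-Hochberg column can be
    appended (the primary analysis is uncorrected).
    """
    profiles = [
        classify(mid, c, t, N1, N2, thresholds, alternative) for mid, (c, t) in sorted(counts.items())
    ]
    df = pd.DataFrame(
        [
            {
                "mirna": p.mirna,
                "count_c": p.count_c,
                "count_t": p.count_t,
                "tpm_c": round(p.tpm_c, 2),
                "tpm_t": round(p.tpm_t, 2),
                "log2fc": round(p.log2fc, 4),
                "p_value": p.p_value,
                "category": p.category,
                "exclusive_flag": p.exclusive_flag,
            }
            for p in profiles
        ]
    )
    if bh_column and len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def category_tally(df: pd.DataFrame) -> pd.DataFrame:
    """Counts of miRNAs per regulation category (plus responsive total)."""
    rows = [{"category": c, "n": int((df["category"] == c).sum())} for c in CATEGORIES]
    responsive = int((df["category"] != "unobvious").sum())
    rows.append({"category": "responsive_total", "n": responsive})
    return pd.DataFrame(rows)
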