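"""Two-rater agreement statistics on paired binary (fire / no-fire) outcomes.

For each rule, the two engines' decisions over a cohort collapse into a 2×2
table: ``a`` visits where both fired, ``b`` where only the first engine
fired, ``c`` where only the second fired, ``d`` where neither did.  From the
table this module computes

* observed agreement  P0 = (a + d) / n,
* Cohen's kappa       κ  = (P0 − Pe) / (1 − Pe),  Pe from the marginals,
* Bias Index          BI = (c − b) / n,
* Prevalence Index    PI = (a − d) / n,
* PABAK (prevalence-adjusted bias-adjusted kappa) = 2·P0 − 1,

with percentile-bootstrap confidence intervals for PABAK and the
Landis–Koch verbal interpretation.  κ is sensitive to both rater bias (b vs
c imbalance) and outcome prevalence (a vs d imbalance); PABAK is the kappa
of the table with both removed, which for two raters reduces to the linear
transform of P0 above.

Note on the BI sign: BI is reported as (c − b)/n, i.e. second-engine firing
proportion minus first-engine firing proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "TwoByTwoTable",
    "AgreementSummary",
    "tabulate",
    "observed_agreement",
    "cohen_kappa",
    "bias_index",
    "prevalence_index",
    "pabak",
    "landis_koch_band",
    "expand_table",
    "bootstrap_ci_pabak",
    "summarize",
    "round_half_away",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Joint fire/no-fire counts for one rule across a cohort."""

    a: int  # both fired
    b: int  # first engine only
    c: int  # second engine only
    d: int  # neither fired

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def _require_nonempty(self) -> None:
        if self.n < 1:
            raise ValueError("statistics are undefined on an empty table (n = 0)")


@dataclass(frozen=True)
class AgreementSummary:
    """All agreement statistics for one rule's table.

    ``kappa`` is None when chance agreement Pe = 1 (both raters constant),
    where κ is undefined.  ``band`` interprets PABAK on the Landis–Koch
    scale.  Values are kept at full precision; round only for presentation.
    """

    table: TwoByTwoTable
    p0: float
    kappa: Optional[float]
    bias_index: float
    prevalence_index: float
    pabak: float
    ci_low: float
    ci_high: float
    band: str


def tabulate(
    outputs_first: Sequence[bool], outputs_second: Sequence[bool]
) -> TwoByTwoTable:
    """Collapse two aligned fired-flag sequences into a 2×2 table.

    The sequences must cover the same visits in the same order.
    """
    if len(outputs_first) != len(outputs_second):
        raise ValueError(
            f"paired sequences differ in length: {len(outputs_first)} vs {len(outputs_second)}"
        )
    a = b = c = d = 0
    for f1, f2 in zip(outputs_first, outputs_second):
        if f1 and f2:
            a += 1
        elif f1:
            b += 1
        elif f2:
            c += 1
        else:
            d += 1
    return TwoByTwoTable(a, b, c, d)


def observed_agreement(t: TwoByTwoTable) -> float:
    t._require_nonempty()
    return (t.a + t.d) / t.n


def _chance_agreement(t: TwoByTwoTable) -> float:
    n = t.n
    return ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / (n * n)


def cohen_kappa(t: TwoByTwoTable) -> Optional[float]:
    """Chance-corrected agreement; None (not an exception) when Pe = 1."""
    t._require_nonempty()
    pe = _chance_agreement(t)
    if pe == 1.0:
        return None
    return (observed_agreement(t) - pe) / (1.0 - pe)


def bias_index(t: TwoByTwoTable) -> float:
    t._require_nonempty()
    return (t.c - t.b) / t.n


def prevalence_index(t: TwoByTwoTable) -> float:
    t._require_nonempty()
    return (t.a - t.d) / t.n


def pabak(t: TwoByTwoTable) -> float:
    t._require_nonempty()
    return 2.0 * observed_agreement(t) - 1.0


_BANDS: Tuple[Tuple[float, str], ...] = (
    (0.80, "almost perfect"),
    (0.60, "substantial"),
    (0.40, "moderate"),
    (0.20, "fair"),
    (0.00, "slight"),
)


def landis_koch_band(value: float) -> str:
    """Landis–Koch verbal label for an agreement coefficient in [-1, 1].

    Cut-points 0.81/0.61/0.41/0.21/0.01 on the two-decimal scale; values at
    or below zero sit below the published scale and are labelled
    "poor/none".
    """
    if math.isnan(value) or not -1.0 <= value <= 1.0:
        raise ValueError(f"agreement coefficient must lie in [-1, 1], got {value!r}")
    for lo, label in _BANDS:
        if value > lo:
            return label
    return "poor/none"


def expand_table(t: TwoByTwoTable) -> List[Tuple[bool, bool]]:
    """Deterministically expand a table into its n paired outcomes.

    Inverse of :func:`tabulate` up to ordering: a (True, True) pairs, then b
    (True, False), c (False, True), d (False, False).
    """
    t._require_nonempty()
    return (
        [(True, True)] * t.a
        + [(True, False)] * t.b
        + [(False, True)] * t.c
        + [(False, False)] * t.d
    )


def bootstrap_ci_pabak(
    pairs: Sequence[Tuple[bool, bool]],
    replicates: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile-bootstrap CI for PABAK from paired outcomes.

    Visits are resampled with replacement ``replicates`` times; PABAK is
    recomputed on each resample and the interval is the (alpha/2,
    1 − alpha/2) percentile pair.  Because PABAK depends on the resample
    only through its cell counts, resampling is done as a multinomial draw
    over the four cells, which is distributionally identical to resampling
    indices and far cheaper.  Deterministic for a fixed seed.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("bootstrap requires at least 2 paired outcomes")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    t = tabulate([p[0] for p in pairs], [p[1] for p in pairs])
    probs = np.array([t.a, t.b, t.c, t.d], dtype=float) / n
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs, size=replicates)
    p0 = (counts[:, 0] + counts[:, 3]) / n
    stats = 2.0 * p0 - 1.0
    low, high = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high)


def summarize(
    t: TwoByTwoTable,
    replicates: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> AgreementSummary:
    """Compute every agreement statistic for one table."""
    pk = pabak(t)
    ci_low, ci_high = bootstrap_ci_pabak(expand_table(t), replicates, alpha, seed)
    return AgreementSummary(
        table=t,
        p0=observed_agreement(t),
        kappa=cohen_kappa(t),
        bias_index=bias_index(t),
        prevalence_index=prevalence_index(t),
        pabak=pk,
        ci_low=ci_low,
        ci_high=ci_high,
        band=landis_koch_band(pk),
    )


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (presentation-layer convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
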