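"""Rank-based association of CTC mutation allele frequencies with clinical
variables.

The analysis unit is the tumor-matched CTC variant allele frequency. Two
observation mappings are supported: ``pooled`` treats every variant's AF as
one observation labelled with its patient's clinical group (many points per
patient, the display convention of per-variant scatter plots), and
``patient_median`` summarizes each patient to one median AF (the patient is
then the exchangeable unit, which is the statistically conservative choice
given within-patient correlation of AFs).

Tests: CEA dichotomized at 5 ng/ml and MSI status use the Mann-Whitney rank
sum test (implemented here, with exact small-sample enumeration); Dukes'
stage with more than two levels uses Kruskal-Wallis; age uses Spearman rank
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .panel import ClinicalRecord

__all__ = [
    "AssociationError",
    "MannWhitneyResult",
    "AssociationResult",
    "mann_whitney_u",
    "associate_af_with_clinical",
    "CEA_ABNORMAL_THRESHOLD",
]

CEA_ABNORMAL_THRESHOLD = 5.0  # ng/ml; >= 5 is conventionally abnormal


class AssociationError(ValueError):
    """The association is undefined (empty group, missing data, ...)."""


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> Tuple[int, ...]:
    """Frequencies of U = 0..n*m over all C(n+m, n) rank arrangements."""
    if n == 0 or m == 0:
        return (1,)
    with_last = _u_counts(n - 1, m)  # largest rank goes to x: U gains m
    without = _u_counts(n, m - 1)  # largest rank goes to y
    out = [0] * (n * m + 1)
    for u, c in enumerate(with_last):
        out[u + m] += c
    for u, c in enumerate(without):
        out[u] += c
    return tuple(out)


def _exact_two_sided_p(u: float, n: int, m: int) -> float:
    """P(|U - nm/2| >= |u - nm/2|) under the exact null distribution."""
    counts = _u_counts(n, m)
    center = n * m / 2.0
    dev = abs(u - center)
    num = sum(c for uu, c in enumerate(counts) if abs(uu - center) >= dev - 1e-12)
    return num / math.comb(n + m, n)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p_value: float
    exact: bool

    def __iter__(self):  # allow ``U, p = mann_whitney_u(x, y)``
        return iter((self.u, self.p_value))


EXACT_MAX_GROUP = 8  # exact enumeration when min(n, m) <= 8 and no ties


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney rank sum test.

    U is computed from the rank sum of ``x`` with midrank tie handling. With
    ``min(n, m) <= 8`` and no ties the p-value comes from exact enumeration
    of the rank-arrangement distribution; otherwise from the normal
    approximation with tie-corrected variance and continuity correction.
    Degenerate input where every value is identical yields p = 1.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise AssociationError("both groups must be non-empty")
    combined = np.asarray(x + y, dtype=float)
    ranks = sps.rankdata(combined)
    r1 = float(ranks[:n].sum())
    u = r1 - n * (n + 1) / 2.0

    has_ties = len(np.unique(combined)) < n + m
    if not has_ties and min(n, m) <= EXACT_MAX_GROUP:
        return MannWhitneyResult(u=u, p_value=_exact_two_sided_p(u, n, m), exact=True)

    N = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # every value identical
        return MannWhitneyResult(u=u, p_value=1.0, exact=False)
    mu = n * m / 2.0
    dev = u - mu
    cc = 0.5 if dev > 0 else (-0.5 if dev < 0 else 0.0)
    z = (dev - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return MannWhitneyResult(u=u, p_value=max(p, 0.0), exact=False)


# ---------------------------------------------------------------------------
# Clinical association
# ---------------------------------------------------------------------------

VALID_VARIABLES = ("CEA", "DUKES", "MSI", "AGE")


@dataclass
class AssociationResult:
    variable: str
    test_name: str
    statistic: float
    p_value: float
    group_sizes: Dict[str, int]
    direction: Optional[str]
    mode: str

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _observations(
    afs_by_patient: Mapping[str, Sequence[float]],
    clinical: Mapping[str, ClinicalRecord],
    mode: str,
) -> List[Tuple[ClinicalRecord, float]]:
    if mode not in ("pooled", "patient_median"):
        raise ValueError(f"mode must be 'pooled' or 'patient_median', got {mode!r}")
    obs: List[Tuple[ClinicalRecord, float]] = []
    for pid in sorted(afs_by_patient):
        afs = [float(a) for a in afs_by_patient[pid]]
        if not afs or pid not in clinical:
            continue
        rec = clinical[pid]
        if mode == "pooled":
            obs.extend((rec, a) for a in afs)
        else:
            obs.append((rec, float(np.median(afs))))
    return obs


def associate_af_with_clinical(
    afs_by_patient: Mapping[str, Sequence[float]],
    clinical: Sequence[ClinicalRecord] | Mapping[str, ClinicalRecord],
    variable: str,
    mode: str = "pooled",
) -> AssociationResult:
    """Associate somatic-mutation allele frequencies with a clinical variable.

    ``afs_by_patient`` maps patient id to the tumor-matched CTC variant AFs
    of that patient (patients without calls contribute nothing). Patients
    with a missing value of the requested variable are excluded. CEA is
    dichotomized at 5 ng/ml.
    """
    variable = variable.upper()
    if variable not in VALID_VARIABLES:
        raise ValueError(f"variable must be one of {VALID_VARIABLES}, got {variable!r}")
    if not isinstance(clinical, Mapping):
        clinical = {r.patient_id: r for r in clinical}
    obs = _observations(afs_by_patient, clinical, mode)

    if variable == "AGE":
        pairs = [(rec.age, af) for rec, af in obs if rec.age is not None]
        if len(pairs) < 3:
            raise AssociationError("need >= 3 observations with age for Spearman")
        ages, afs = zip(*pairs)
        rho, p = sps.spearmanr(ages, afs)
        if not np.isfinite(rho) or not np.isfinite(p):
            raise AssociationError("Spearman correlation undefined (constant input)")
        return AssociationResult(
            variable="AGE",
            test_name="spearman",
            statistic=float(rho),
            p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
            group_sizes={"n": len(pairs)},
            direction="positive" if rho > 0 else ("negative" if rho < 0 else None),
            mode=mode,
        )

    def group_of(rec: ClinicalRecord) -> Optional[str]:
        if variable == "CEA":
            if rec.cea is None:
                return None
            return (
                f"CEA>={CEA_ABNORMAL_THRESHOLD:g}"
                if rec.cea >= CEA_ABNORMAL_THRESHOLD
                else f"CEA<{CEA_ABNORMAL_THRESHOLD:g}"
            )
        if variable == "MSI":
            return rec.msi
        return rec.dukes  # DUKES

    groups: Dict[str, List[float]] = {}
    for rec, af in obs:
        g = group_of(rec)
        if g is not None:
            groups.setdefault(g, []).append(af)
    groups = {g: v for g, v in sorted(groups.items()) if v}
    if len(groups) < 2:
        raise AssociationError(
            f"fewer than 2 non-empty groups for {variable} after exclusions"
        )
    sizes = {g: len(v) for g, v in groups.items()}

    if len(groups) == 2:
        (ga, xa), (gb, xb) = groups.items()
        res = mann_whitney_u(xa, xb)
        # direction: group whose observations rank higher
        expected_u = len(xa) * len(xb) / 2.0
        direction = ga if res.u > expected_u else (gb if res.u < expected_u else None)
        return AssociationResult(
            variable=variable,
            test_name="mann-whitney",
            statistic=res.u,
            p_value=res.p_value,
            group_sizes=sizes,
            direction=direction,
            mode=mode,
        )

    h, p = sps.kruskal(*groups.values())
    medians = {g: float(np.median(v)) for g, v in groups.items()}
    return AssociationResult(
        variable=variable,
        test_name="kruskal-wallis",
        statistic=float(h),
        p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
        group_sizes=sizes,
        direction=max(medians, key=medians.get),
        mode=mode,
    )
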