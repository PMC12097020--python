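"""Antigen-panel coverage scoring and max-coverage panel selection.

Coverage of a panel is the fraction of (malignant) cells positive for at
least one panel antigen — the union-of-positives statistic. Panels of size
k <= 3 are scored exhaustively over the target bank ("dual" and "triple"
combinations; four-target panels are deliberately not enumerated by default,
matching the clinical design scope); a greedy max-coverage heuristic with
the classic (1 - 1/e) guarantee is provided for larger banks. A panel is
recommended per patient as the smallest k in [k_min, k_max] whose best
panel meets the per-k coverage threshold (defaults: 80% for pairs, 90% for
triples).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .qc import PositivityMatrix

#: Largest panel size enumerated without an explicit override.
DEFAULT_K_CAP = 3

#: Default per-k required coverage for a panel to be "recommended".
DEFAULT_THRESHOLDS = {2: 0.80, 3: 0.90}


def canonical_panel(antigens: Iterable[str]) -> tuple[str, ...]:
    """Canonical (lexicographically sorted, unique) form of a panel."""
    panel = tuple(sorted(set(antigens)))
    if len(panel) == 0:
        raise InputError("a panel must contain at least one antigen")
    return panel


@dataclass(frozen=True)
class CoverageThresholds:
    """Required coverage per panel size k, values in (0, 1]."""

    per_k: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        for k, v in self.per_k.items():
            if not 0 < v <= 1:
                raise ConfigurationError(f"threshold for k={k} must be in (0, 1]")

    def require(self, k: int) -> float:
        if k not in self.per_k:
            raise ConfigurationError(f"no coverage threshold configured for k={k}")
        return self.per_k[k]


@dataclass
class CoverageResult:
    """A panel with its covered-cell fraction and per-antigen marginals."""

    panel: tuple[str, ...]
    coverage: float
    covered_cells: int
    n_cells: int
    marginals: dict[str, float]

    def __post_init__(self) -> None:
        assert self.n_cells > 0
        assert abs(self.coverage - self.covered_cells / self.n_cells) < 1e-12

    @property
    def k(self) -> int:
        return len(self.panel)


@dataclass
class Recommendation:
    """Per-patient panel choice with the threshold verdict."""

    patient_id: str
    panel: tuple[str, ...]
    k: int
    coverage: float
    threshold: float
    met: bool
    alternatives: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "panel": list(self.panel),
            "k": self.k,
            "coverage": self.coverage,
            "threshold": self.threshold,
            "met": self.met,
            "alternatives": [
                {"panel": list(p), "coverage": c} for p, c in self.alternatives
            ],
        }


def _validate_panel(P: PositivityMatrix, panel: Sequence[str]) -> tuple[str, ...]:
    panel = canonical_panel(panel)
    unknown = [a for a in panel if a not in P.flags.columns]
    if unknown:
        raise InputError(f"antigens not in the positivity matrix: {unknown}")
    return panel


def coverage(P: PositivityMatrix, panel: Sequence[str]) -> CoverageResult:
    """Union coverage: fraction of cells positive for >= 1 panel antigen."""
    panel = _validate_panel(P, panel)
    sub = P.flags[list(panel)].to_numpy()
    covered = int(sub.any(axis=1).sum())
    marginals = {a: float(P.flags[a].mean()) for a in panel}
    return CoverageResult(
        panel=panel,
        coverage=covered / P.n_cells,
        covered_cells=covered,
        n_cells=P.n_cells,
        marginals=marginals,
    )


def enumerate_panels(
    P: PositivityMatrix,
    k: int,
    bank: Sequence[str] | None = None,
    k_cap: int = DEFAULT_K_CAP,
    allow_large: bool = False,
) -> list[CoverageResult]:
    """Score every size-k panel over the bank, best coverage first.

    Returns exactly C(|bank|, k) results sorted by coverage descending,
    ties broken by canonical (lexicographic) panel order. Panels larger
    than ``k_cap`` (default 3) are refused unless ``allow_large``.
    """
    bank = sorted(set(bank)) if bank is not None else P.antigens
    if not 1 <= k <= len(bank):
        raise InputError(f"k must be in [1, {len(bank)}], got {k}")
    if k > k_cap and not allow_large:
        raise ConfigurationError(
            f"panels of size {k} exceed the configured cap of {k_cap} "
            "(combinations beyond triples are not enumerated by default); "
            "pass allow_large=True to override"
        )
    unknown = [a for a in bank if a not in P.flags.columns]
    if unknown:
        raise InputError(f"bank antigens not in the positivity matrix: {unknown}")

    flags = P.flags[bank].to_numpy(dtype=bool)
    n = P.n_cells
    results = []
    for combo in itertools.combinations(range(len(bank)), k):
        covered = int(flags[:, combo].any(axis=1).sum())
        panel = tuple(bank[i] for i in combo)
        results.append(
            CoverageResult(
                panel=panel,
                coverage=covered / n,
                covered_cells=covered,
                n_cells=n,
                marginals={a: float(flags[:, bank.index(a)].mean()) for a in panel},
            )
        )
    results.sort(key=lambda r: (-r.coverage, r.panel))
    return results


def greedy_panel(P: PositivityMatrix, k: int, bank: Sequence[str] | None = None) -> CoverageResult:
    """Greedy max-coverage: repeatedly add the antigen covering the most
    still-uncovered cells (ties broken lexicographically). Deterministic;
    achieves >= (1 - 1/e) of the exhaustive optimum.
    """
    bank = sorted(set(bank)) if bank is not None else P.antigens
    if k < 1:
        raise InputError("k must be >= 1")
    if k > len(bank):
        raise InputError(f"k={k} exceeds the bank size {len(bank)}")
    flags = {a: P.flags[a].to_numpy(dtype=bool) for a in bank}
    chosen: list[str] = []
    covered = np.zeros(P.n_cells, dtype=bool)
    for _ in range(k):
        best_a, best_gain = None, -1
        for a in bank:  # bank is sorted, so first max wins ties lexicographically
            if a in chosen:
                continue
            gain = int((flags[a] & ~covered).sum())
            if gain > best_gain:
                best_a, best_gain = a, gain
        chosen.append(best_a)
        covered |= flags[best_a]
    return coverage(P, chosen)


def recommend_panel(
    P: PositivityMatrix,
    thresholds: CoverageThresholds = CoverageThresholds(),
    k_min: int = 2,
    k_max: int = 3,
    patient_id: str = "",
    bank: Sequence[str] | None = None,
    k_cap: int = DEFAULT_K_CAP,
    n_alternatives: int = 5,
) -> Recommendation:
    """Choose the smallest panel size whose best panel meets its threshold.

    Scans k = k_min .. k_max; at the first k whose coverage-maximal panel
    reaches the per-k threshold (inclusive: coverage 0.80 meets an 0.80
    bar), that panel is recommended with ``met=True``. If no k qualifies,
    the best k_max panel is returned with ``met=False``.
    """
    if not 1 <= k_min <= k_max <= k_cap:
        raise ConfigurationError("need 1 <= k_min <= k_max <= k_cap")
    for k in range(k_min, k_max + 1):
        thresholds.require(k)  # fail fast if any k in range is unconfigured
    last_ranked: list[CoverageResult] = []
    for k in range(k_min, k_max + 1):
        ranked = enumerate_panels(P, k, bank=bank, k_cap=k_cap)
        best = ranked[0]
        thr = thresholds.require(k)
        if best.coverage >= thr:
            return Recommendation(
                patient_id=patient_id,
                panel=best.panel,
                k=k,
                coverage=best.coverage,
                threshold=thr,
                met=True,
                alternatives=[(r.panel, r.coverage) for r in ranked[1 : n_alternatives + 1]],
            )
        last_ranked = ranked
    best = last_ranked[0]
    return Recommendation(
        patient_id=patient_id,
        panel=best.panel,
        k=k_max,
        coverage=best.coverage,
        threshold=thresholds.require(k_max),
        met=False,
        alternatives=[(r.panel, r.coverage) for r in last_ranked[1 : n_alternatives + 1]],
    )


def cohort_summary(
    per_patient: Mapping[str, Sequence[CoverageResult]],
) -> pd.DataFrame:
    """Per-panel mean and SD of coverage across patients.

    Panels must align across patients. SD uses the n-1 denominator; with a
    single patient it is reported as 0 and flagged ``degenerate_n``. Sorted
    by mean coverage descending (canonical panel order on ties), so the
    first row is the highest-average panel.
    """
    if not per_patient:
        raise InputError("cohort_summary needs at least one patient")
    panel_sets = {
        pid: tuple(sorted(r.panel for r in results))
        for pid, results in per_patient.items()
    }
    ref = next(iter(panel_sets.values()))
    bad = [pid for pid, s in panel_sets.items() if s != ref]
    if bad:
        raise InputError(f"panel sets differ across patients (e.g. {bad[0]})")
    rows = []
    panels = ref
    by_patient = {
        pid: {r.panel: r.coverage for r in results}
        for pid, results in per_patient.items()
    }
    n = len(by_patient)
    for panel in panels:
        vals = np.array([by_patient[pid][panel] for pid in sorted(by_patient)])
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "panel": "+".join(panel),
                "k": len(panel),
                "mean_coverage": float(vals.mean()),
                "sd_coverage": sd,
                "n_patients": n,
                "degenerate_n": n == 1,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["mean_coverage", "panel"], ascending=[False, True], ignore_index=True
    )
    return df


def rank_sum_pvalue(tumor: Sequence[float], normal: Sequence[float]) -> float:
    """One-sided Wilcoxon rank-sum p-value for tumor > normal.

    Exact enumeration when both groups have n <= 10 and no cross-group ties;
    otherwise the normal approximation with tie correction.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.size == 0 or normal.size == 0:
        raise InputError("expression vectors must be non-empty")
    combined = np.concatenate([tumor, normal])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (tumor.size <= 10 and normal.size <= 10 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(tumor, normal, alternative="greater", method=method).pvalue
    )


def screen_target_bank(
    catalog: pd.DataFrame,
    alpha: float = 0.05,
    min_expression_rate: float = 0.70,
) -> pd.DataFrame:
    """Screen a candidate-antigen catalog down to the working target pool.

    An antigen is retained iff its literature expression rate strictly
    exceeds ``min_expression_rate``, its protein expression is flagged
    stable, and tumor expression exceeds normal by a one-sided rank-sum
    test at strictly ``p < alpha``.

    ``catalog`` columns: antigen, expression_rate, stability_flag,
    tumor_expr, normal_expr (the last two holding per-row numeric vectors).
    """
    required = {"antigen", "expression_rate", "stability_flag", "tumor_expr", "normal_expr"}
    missing = required - set(catalog.columns)
    if missing:
        raise InputError(f"catalog is missing columns: {sorted(missing)}")
    out = catalog.copy()
    pvals = []
    for _, row in out.iterrows():
        if row["expression_rate"] > min_expression_rate and bool(row["stability_flag"]):
            pvals.append(rank_sum_pvalue(row["tumor_expr"], row["normal_expr"]))
        else:
            pvals.append(np.nan)  # test not evaluated for pre-excluded antigens
    out["rank_sum_p"] = pvals
    out["retained"] = (
        (out["expression_rate"] > min_expression_rate)
        & out["stability_flag"].astype(bool)
        & (out["rank_sum_p"] < alpha)
    )
    pool = out[out["retained"]].reset_index(drop=True)
    if pool.empty:
        warnings.warn("all antigens excluded by the screening criteria")
    return pool
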