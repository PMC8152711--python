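"""Screening-performance measures against the reference standard.

Notation (all counts over one corpus of N abstracts):

* ``N_S``  - abstracts eligible per the reference standard (two human
  reviewers screening everything),
* ``N_P``  - abstracts the workflow ever predicted eligible,
* ``N_WF`` - eligible abstracts the workflow confirmed (eligible per the
  reference standard among workflow-identified inclusions),
* ``dN = N_S - N_WF`` - eligible abstracts the workflow missed.

Percentages: precision = 100*N_WF/N_P, sensitivity (recall) = 100*N_WF/N_S,
F1 the harmonic mean of the two. Specificity and accuracy come from the
standard confusion matrix over all N documents with "predicted eligible" =
ever-predicted; the alternative specificity formula 100*(N-N_WF)/(N-N_S)
seen in some screening reports exceeds 100% whenever the workflow misses
anything, so it is reported separately for comparison, never used.

Workload reduction counts the abstracts never shown to human reviewers;
person-hours saved assume two reviewers at 200 abstracts per reviewer-hour.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Optional, TYPE_CHECKING

ABSTRACTS_PER_REVIEWER_HOUR = 200
REVIEWERS_PER_ABSTRACT = 2

if TYPE_CHECKING:  # pragma: no cover
    from .engine import WorkflowResult


@dataclass
class EvalReport:
    N: int
    N_P: int
    N_WF: int
    N_S: int
    delta_N: int
    precision_pct: Optional[float]
    sensitivity_pct: Optional[float]
    f1_pct: Optional[float]
    specificity_pct: float
    accuracy_pct: float
    specificity_alt_formula_pct: Optional[float]
    n_screened: int
    workload_reduction_pct: float
    hours_saved: float
    undefined: tuple = ()

    def rounded(self) -> dict:
        """Integer-percent presentation (report-table style); raw values kept."""
        out = {}
        for key, val in asdict(self).items():
            if key.endswith("_pct") and val is not None:
                out[key] = round(val)
            else:
                out[key] = val
        out["hours_saved"] = round(self.hours_saved)
        return out

    def summary(self) -> str:
        r = self.rounded()
        lines = [
            f"N={self.N}  N_P={self.N_P}  N_WF={self.N_WF}  N_S={self.N_S}  dN={self.delta_N}",
            f"precision={r['precision_pct']}%  sensitivity={r['sensitivity_pct']}%  F1={r['f1_pct']}%",
            f"specificity={self.specificity_pct:.1f}%  accuracy={r['accuracy_pct']}%",
            f"screened={self.n_screened}/{self.N}  workload reduction={r['workload_reduction_pct']}%"
            f"  hours saved={self.hours_saved:.1f}",
        ]
        if self.undefined:
            lines.append(f"undefined metrics: {', '.join(self.undefined)}")
        return "\n".join(lines)


def workload_and_hours(N: int, n_screened: int) -> tuple[float, float]:
    """Workload reduction (% of corpus never screened) and person-hours saved."""
    if not (0 <= n_screened <= N):
        raise ValueError(f"n_screened must lie in [0, N]; got {n_screened} with N={N}")
    unscreened = N - n_screened
    reduction_pct = 100.0 * unscreened / N if N else 0.0
    hours = REVIEWERS_PER_ABSTRACT * unscreened / ABSTRACTS_PER_REVIEWER_HOUR
    return reduction_pct, hours


def f1_from_counts(precision_pct: float, sensitivity_pct: float) -> float:
    """Harmonic mean of precision and sensitivity, on the percent scale."""
    if precision_pct + sensitivity_pct == 0:
        return 0.0
    return 2.0 * precision_pct * sensitivity_pct / (precision_pct + sensitivity_pct)


def metrics_from_counts(
    n_wf: int, n_s: int, n_p: Optional[int] = None
) -> dict:
    """Precision/sensitivity/F1 arithmetic from raw counts (percent scale)."""
    out: dict = {"N_WF": n_wf, "N_S": n_s, "delta_N": n_s - n_wf}
    out["sensitivity_pct"] = 100.0 * n_wf / n_s if n_s else None
    if n_p is not None:
        out["N_P"] = n_p
        out["precision_pct"] = 100.0 * n_wf / n_p if n_p else None
        if out["precision_pct"] is not None and out["sensitivity_pct"] is not None:
            out["f1_pct"] = f1_from_counts(out["precision_pct"], out["sensitivity_pct"])
    return out


def missed_study_error_rate(n_missed: int, n_included: int) -> float:
    """Percent of included studies lost by screening only workflow inclusions."""
    if n_included <= 0:
        raise ValueError("n_included must be positive")
    return 100.0 * n_missed / n_included


def compute_metrics(
    result: "WorkflowResult", reference: Mapping[str, int], N: Optional[int] = None
) -> EvalReport:
    """Score a workflow run against the reference standard.

    ``reference`` must label every corpus document. The confusion matrix for
    specificity/accuracy uses ever-predicted as the positive call; precision
    and sensitivity use the workflow-confirmed count N_WF as in the report
    conventions above. Zero denominators yield flagged ``None`` values,
    never division errors.
    """
    if N is None:
        N = len(reference)
    eligible = {d for d, lab in reference.items() if lab == 1}
    n_s = len(eligible)
    predicted = set(result.predicted_ever)
    n_p = len(predicted)
    included = set(result.included)
    n_wf = len(included & eligible)

    undefined = []
    precision = 100.0 * n_wf / n_p if n_p else None
    if precision is None:
        undefined.append("precision")
    sensitivity = 100.0 * n_wf / n_s if n_s else None
    if sensitivity is None:
        undefined.append("sensitivity")
    f1 = (
        f1_from_counts(precision, sensitivity)
        if precision is not None and sensitivity is not None
        else None
    )
    if f1 is None and "precision" not in undefined and "sensitivity" not in undefined:
        undefined.append("f1")

    tp = len(predicted & eligible)
    fp = n_p - tp
    fn = n_s - tp
    tn = N - tp - fp - fn
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) else 100.0
    accuracy = 100.0 * (tp + tn) / N if N else 100.0
    alt_spec = 100.0 * (N - n_wf) / (N - n_s) if N != n_s else None

    n_screened = len(set(result.screened))
    reduction, hours = workload_and_hours(N, n_screened)
    return EvalReport(
        N=N, N_P=n_p, N_WF=n_wf, N_S=n_s, delta_N=n_s - n_wf,
        precision_pct=precision, sensitivity_pct=sensitivity, f1_pct=f1,
        specificity_pct=specificity, accuracy_pct=accuracy,
        specificity_alt_formula_pct=alt_spec,
        n_screened=n_screened, workload_reduction_pct=reduction, hours_saved=hours,
        undefined=tuple(undefined),
    )
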