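"""Time and monetary cost of the three grading strategies.

Compares, over a dataset of ``n_total`` images of which ``n_reviewed`` are
flagged for human regrading:

* **fully human** — every image graded by humans;
* **fully automated** — every image graded by the classifier only
  (monetary cost zero by default: the marginal cost of running a trained
  model is negligible, and development cost is out of scope);
* **semi-automated** — the classifier grades everything, humans regrade
  the flagged subset: machine time over all images plus human time (and
  pay) over the reviewed images.

Savings of the semi-automated strategy relative to fully human grading are
1 - semi/full per dimension, computed from full-precision totals.
Because published comparisons typically quote per-image means at printed
precision, :func:`rounded_savings` recomputes the savings from the means
rounded as a report would print them (time to 2 decimals of a minute, cost
to 3 decimals of a dollar); the two routes can differ by a point or so.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CostParams", "StrategyCost", "CostReport", "cost_evaluate",
           "rounded_savings"]


@dataclass(frozen=True)
class CostParams:
    """Per-image unit times (minutes) and unit costs (currency)."""

    t_machine: float = 0.058
    t_human: float = 0.368
    c_human: float = 0.172
    machine_marginal_cost: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t_machine", "t_human", "c_human",
                     "machine_marginal_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class StrategyCost:
    """Totals and per-image means for one grading strategy."""

    total_time_hours: float
    mean_time_min_per_image: float
    total_cost: float
    mean_cost_per_image: float


@dataclass(frozen=True)
class CostReport:
    """Costs of the three strategies plus semi-vs-human saving fractions."""

    n_total: int
    n_reviewed: int
    fully_human: StrategyCost
    fully_auto: StrategyCost
    semi_auto: StrategyCost
    saving_time_fraction: float
    saving_cost_fraction: float

    def as_dict(self) -> dict:
        out: dict = {"n_total": self.n_total, "n_reviewed": self.n_reviewed}
        for name in ("fully_human", "fully_auto", "semi_auto"):
            s: StrategyCost = getattr(self, name)
            out[name] = {
                "total_time_hours": s.total_time_hours,
                "mean_time_min_per_image": s.mean_time_min_per_image,
                "total_cost": s.total_cost,
                "mean_cost_per_image": s.mean_cost_per_image,
            }
        out["saving_time_fraction"] = self.saving_time_fraction
        out["saving_cost_fraction"] = self.saving_cost_fraction
        return out


def _strategy(n_imgs_machine: int, n_imgs_human: int, n_total: int,
              p: CostParams) -> StrategyCost:
    total_min = n_imgs_machine * p.t_machine + n_imgs_human * p.t_human
    total_cost = (n_imgs_machine * p.machine_marginal_cost
                  + n_imgs_human * p.c_human)
    return StrategyCost(
        total_time_hours=total_min / 60.0,
        mean_time_min_per_image=total_min / n_total,
        total_cost=total_cost,
        mean_cost_per_image=total_cost / n_total)


def cost_evaluate(n_total: int, n_reviewed: int,
                  params: CostParams) -> CostReport:
    """Evaluate all three strategies for a run of the workflow.

    Raises
    ------
    ValueError
        If ``n_reviewed > n_total`` or counts are invalid.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_reviewed <= n_total:
        raise ValueError("n_reviewed must lie in [0, n_total]")
    human = _strategy(0, n_total, n_total, params)
    auto = _strategy(n_total, 0, n_total, params)
    semi = StrategyCost(
        total_time_hours=(n_total * params.t_machine
                          + n_reviewed * params.t_human) / 60.0,
        mean_time_min_per_image=(n_total * params.t_machine
                                 + n_reviewed * params.t_human) / n_total,
        total_cost=(n_total * params.machine_marginal_cost
                    + n_reviewed * params.c_human),
        mean_cost_per_image=(n_total * params.machine_marginal_cost
                             + n_reviewed * params.c_human) / n_total)
    save_t = (1.0 - semi.total_time_hours / human.total_time_hours
              if human.total_time_hours > 0 else 0.0)
    save_c = (1.0 - semi.total_cost / human.total_cost
              if human.total_cost > 0 else 0.0)
    return CostReport(n_total=n_total, n_reviewed=n_reviewed,
                      fully_human=human, fully_auto=auto, semi_auto=semi,
                      saving_time_fraction=save_t,
                      saving_cost_fraction=save_c)


def rounded_savings(report: CostReport, *, time_decimals: int = 2,
                    cost_decimals: int = 3) -> tuple[float, float]:
    """Savings recomputed from per-image means at printed precision.

    Returns ``(time_saving, cost_saving)`` where each saving is
    1 - round(semi mean) / round(fully-human mean). This is how a reader
    reproduces the savings from a published per-image table, and it can
    differ from the full-precision fractions by rounding alone.
    """
    ht = round(report.fully_human.mean_time_min_per_image, time_decimals + 1)
    st = round(report.semi_auto.mean_time_min_per_image, time_decimals)
    hc = round(report.fully_human.mean_cost_per_image, cost_decimals)
    sc = round(report.semi_auto.mean_cost_per_image, cost_decimals)
    save_t = 1.0 - st / ht if ht > 0 else 0.0
    save_c = 1.0 - sc / hc if hc > 0 else 0.0
    return save_t, save_c
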