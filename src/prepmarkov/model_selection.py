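"""Full-covariate model construction and backward elimination on OR intervals.

The full model assigns every screened-in covariate to both transition logits.
Reduction then iterates: fit, compute 95% Wald confidence intervals on the
odds-ratio scale, drop every effect whose interval contains 1, refit — until
no effect drops.  Elimination is per effect (covariate x logit), so a
covariate may survive on one logit only; simultaneous removal within an
iteration is the default, one-at-a-time (largest p-value first) is an option.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .errors import ConfigurationError
from .markov_model import (EffectEstimate, FitResult, ModelSpec,
                           MarkovTransitionModel, odds_ratios)
from .transitions import ScreenResult, TransitionDataset

logger = logging.getLogger(__name__)


def full_model_spec(
    covariate_names: list[str],
    screened: dict[str, ScreenResult] | None = None,
    *,
    random_effects: str = "separate",
    method: str = "laplace",
    nodes: int = 9,
) -> ModelSpec:
    """Model spec with every retained covariate on both the P01 and P10 logits.

    ``screened`` maps covariate names to sparse-transition screen results;
    flagged covariates are excluded.  Indicator columns of a multi-level
    covariate enter as separate terms (one effect per non-reference level).
    """
    if not covariate_names:
        raise ConfigurationError("empty covariate registry")
    kept = [c for c in covariate_names
            if screened is None or c not in screened or screened[c].keep]
    return ModelSpec(tuple(kept), tuple(kept), random_effects, method, nodes)


@dataclass
class IterationRecord:
    """One fit-and-prune step of the elimination."""

    spec: ModelSpec
    effects: list[EffectEstimate]
    dropped: list[dict] = field(default_factory=list)
    neg2ll: float = float("nan")
    converged: bool = True


@dataclass
class SelectionHistory:
    """Ordered record of every elimination iteration."""

    iterations: list[IterationRecord] = field(default_factory=list)
    halted_on_nonconvergence: bool = False

    def to_json(self, path=None) -> str:
        payload = {
            "halted_on_nonconvergence": self.halted_on_nonconvergence,
            "iterations": [
                {
                    "p01_terms": list(it.spec.p01_terms),
                    "p10_terms": list(it.spec.p10_terms),
                    "neg2ll": it.neg2ll,
                    "converged": it.converged,
                    "effects": [
                        {"effect": e.name, "parameter": e.target,
                         "OR": e.odds_ratio, "ci_low": e.ci_low,
                         "ci_high": e.ci_high}
                        for e in it.effects
                    ],
                    "dropped": it.dropped,
                }
                for it in self.iterations
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _failing(effects: list[EffectEstimate]) -> list[EffectEstimate]:
    """Effects whose 95% CI on the OR scale contains unity (or has no CI)."""
    out = []
    for e in effects:
        if e.ci_low is None or e.ci_high is None:
            out.append(e)       # no SE: cannot defend the effect, drop it
        elif e.ci_low <= 1.0 <= e.ci_high:
            out.append(e)
    return out


def backward_eliminate(
    dataset: TransitionDataset,
    spec: ModelSpec,
    *,
    mode: str = "simultaneous",
    **fit_kwargs,
) -> tuple[FitResult, SelectionHistory]:
    """Reduce a full model by the unity-in-CI rule until no effect drops.

    ``mode="simultaneous"`` (default) drops every failing effect in one
    iteration; ``mode="sequential"`` drops only the weakest failing effect
    (smallest |beta|/SE) per iteration.  Terminates in at most one iteration
    per effect.  Non-convergence at any step records the failure and halts
    with the last available fit.
    """
    if mode not in ("simultaneous", "sequential"):
        raise ConfigurationError(f"unknown elimination mode {mode!r}")
    history = SelectionHistory()
    current = spec
    result: FitResult | None = None
    max_iter = len(spec.effects()) + 1
    for _ in range(max_iter):
        est = MarkovTransitionModel(
            p01_terms=tuple(current.p01_terms),
            p10_terms=tuple(current.p10_terms),
            random_effects=current.random_effects,
            method=current.method, nodes=current.nodes, **fit_kwargs)
        result = est.fit(dataset).result_
        effects = odds_ratios(result)
        record = IterationRecord(spec=current, effects=effects,
                                 neg2ll=result.neg2ll,
                                 converged=result.converged)
        history.iterations.append(record)
        if not result.converged:
            history.halted_on_nonconvergence = True
            logger.warning("elimination halted: fit did not converge")
            break
        failing = _failing(effects)
        if not failing:
            break
        if mode == "sequential":
            def _z(e: EffectEstimate) -> float:
                if e.se is None or not e.se:
                    return 0.0
                return abs(e.beta) / e.se
            failing = [min(failing, key=_z)]
        for e in failing:
            record.dropped.append({
                "effect": e.name, "parameter": e.target,
                "OR": e.odds_ratio, "ci_low": e.ci_low, "ci_high": e.ci_high,
                "reason": "CI includes unity" if e.ci_low is not None
                          else "no standard error",
            })
            logger.info("dropping %s on %s: OR %.3f, CI (%s, %s)",
                        e.name, e.target.upper(), e.odds_ratio,
                        f"{e.ci_low:.3f}" if e.ci_low is not None else "NA",
                        f"{e.ci_high:.3f}" if e.ci_high is not None else "NA")
        current = current.drop([(d["parameter"], d["effect"])
                                for d in record.dropped])
    assert result is not None
    return result, history
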