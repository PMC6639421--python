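"""Synthetic MEMS-style cohorts with the structure the analysis assumes.

The generator emulates a PrEP demonstration cohort of HIV serodiscordant
couples: ~920 subjects followed ~12 months, daily dose-taking driven by a
covariate-dependent two-state Markov chain with subject-level random effects
on both transition logits.  Covariate prevalences default to the study's
demographic mix (65% male, 80% aged over 25, sex-risk 4/34/62%, 52% with the
partner on ART for 6+ months, 88% wanting the relationship to succeed, 57%
beyond 6 months of follow-up, 20% with problem alcohol use); covariate
effects default to the published odds ratios, the only printed effect sizes.
Intercepts are chosen so a typical subject re-initiates after a missed dose
with probability ~0.27 and discontinues after a taken dose with probability
~0.10, matching the observed dominance of [11] transitions (~65% of all
transitions, stationary adherence ~73%).

The observable outputs are exactly the files the reader consumes — an event
log with one jittered opening timestamp per dose-taking day, a covariate
table and a window file — plus a separately stored truth record (random
effects, latent states, generating parameters) for recovery checks.
Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError
from .io_events import AdherenceSeries, CovariateTable, FollowUpWindow
from .markov_model import MarkovParams

#: Marginal covariate prevalences of the emulated cohort (binary indicators).
DEFAULT_PREVALENCES: dict[str, float] = {
    "age_over_25": 0.80,
    "female": 0.35,
    "partner_art_6m": 0.52,
    "wants_relationship": 0.88,
    "followup_6m": 0.57,
    "problem_alcohol": 0.20,
}

#: Multi-level covariates: level -> probability; the first level is the
#: reference and the others become 0/1 indicator columns named after them.
DEFAULT_MULTINOMIALS: dict[str, dict[str, float]] = {
    "sex_risk": {"no_sex": 0.04, "condom_100": 0.34, "condom_lt100": 0.62},
}

#: Published effect sizes (log odds ratios) used as generating truth.
TRUE_LOG_OR_P01: dict[str, float] = {
    "partner_art_6m": math.log(0.86),
    "wants_relationship": math.log(1.45),
    "followup_6m": math.log(0.80),
    "problem_alcohol": math.log(0.63),
    "condom_lt100": math.log(1.21),
}
TRUE_LOG_OR_P10: dict[str, float] = {
    "age_over_25": math.log(0.61),
    "female": math.log(0.67),
    "partner_art_6m": math.log(1.34),
    "wants_relationship": math.log(0.79),
    "followup_6m": math.log(1.25),
    "problem_alcohol": math.log(1.16),
    "condom_100": math.log(0.84),
    "condom_lt100": math.log(0.69),
}

TYPICAL_P01 = 0.27      # re-initiation probability of a typical subject
TYPICAL_P10 = 0.10      # discontinuation probability of a typical subject
DEFAULT_OMEGA_SQ = (0.5, 0.5)


def _mean_covariates(prevalences, multinomials) -> dict[str, float]:
    mean = dict(prevalences)
    for levels in multinomials.values():
        for i, (lvl, p) in enumerate(levels.items()):
            if i:                      # skip reference level
                mean[lvl] = p
    return mean


def default_true_params(
    prevalences: dict[str, float] | None = None,
    multinomials: dict[str, dict[str, float]] | None = None,
    *,
    typical_p01: float = TYPICAL_P01,
    typical_p10: float = TYPICAL_P10,
    omega_sq: tuple[float, float] = DEFAULT_OMEGA_SQ,
) -> MarkovParams:
    """Generating parameters anchored to the published odds ratios.

    Intercepts are solved so that at the prevalence-mean covariate vector and
    eta = 0 the transition probabilities equal the typical values.
    """
    prevalences = DEFAULT_PREVALENCES if prevalences is None else prevalences
    multinomials = DEFAULT_MULTINOMIALS if multinomials is None else multinomials
    mean = _mean_covariates(prevalences, multinomials)
    shift01 = sum(b * mean.get(k, 0.0) for k, b in TRUE_LOG_OR_P01.items())
    shift10 = sum(b * mean.get(k, 0.0) for k, b in TRUE_LOG_OR_P10.items())
    return MarkovParams(
        theta1=float(logit(typical_p01) - shift01),
        theta2=float(logit(typical_p10) - shift10),
        beta01=dict(TRUE_LOG_OR_P01),
        beta10=dict(TRUE_LOG_OR_P10),
        omega_sq=omega_sq,
        random_effects="separate",
    )


@dataclass
class CohortSpec:
    """Generating conditions for one synthetic cohort."""

    n_subjects: int = 920
    n_days: int = 360
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    multinomials: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MULTINOMIALS.items()})
    true_params: MarkovParams | None = None
    initial_state: int = 1
    start_date: date = date(2015, 1, 1)
    dose_window: tuple[float, float] = (6.0, 22.0)   # clock-hour jitter range
    followup_switch_day: int = 183                   # used by inject_timevarying

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_days < 1:
            raise ConfigurationError("n_subjects and n_days must be >= 1")
        for name, p in self.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence of {name!r} outside [0, 1]")
        for name, levels in self.multinomials.items():
            probs = list(levels.values())
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"multinomial prevalences of {name!r} must be >= 0 and sum to 1")
        if self.true_params is None:
            self.true_params = default_true_params(self.prevalences,
                                                   self.multinomials)

    @property
    def covariate_names(self) -> list[str]:
        names = list(self.prevalences)
        for levels in self.multinomials.values():
            names.extend(list(levels)[1:])
        return names


@dataclass
class SyntheticCohort:
    """Observable files plus hidden truth of one generated cohort."""

    spec: CohortSpec
    events: pd.DataFrame                  # subject_id, timestamp
    covariates: pd.DataFrame              # wide, subject_id column first
    windows: pd.DataFrame                 # subject_id, start_date, end_date
    intervals: pd.DataFrame | None        # long time-varying format, optional
    truth: dict                           # etas, states, generating params

    @property
    def states(self) -> np.ndarray:
        return np.asarray(self.truth["states"], dtype=np.int8)

    def covariate_table(self) -> CovariateTable:
        return CovariateTable(self.covariates, self.intervals)

    def follow_up_windows(self) -> list[FollowUpWindow]:
        return [FollowUpWindow(str(r.subject_id),
                               pd.Timestamp(r.start_date).date(),
                               pd.Timestamp(r.end_date).date())
                for r in self.windows.itertuples(index=False)]

    def to_dataset(self, initial_state: int | None = None):
        """Likelihood-ready dataset built directly from the latent states.

        Bypasses the event-log file round trip (which is exact anyway); per-day
        covariates are resolved through the same machinery the reader uses.
        """
        from .transitions import TransitionDataset
        if initial_state is None:
            initial_state = self.spec.initial_state
        table = self.covariate_table()
        series = []
        frames = []
        states = self.states
        for i, sid in enumerate(self.truth["subject_ids"]):
            s = AdherenceSeries(str(sid), self.spec.start_date, states[i])
            series.append(s)
            frames.append(table.resolve(s))
        return TransitionDataset.from_series(series, frames,
                                             initial_state=initial_state)

    def write(self, outdir) -> dict[str, Path]:
        """Emit event log, covariates, windows (CSV) and truth (JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "events": outdir / "events.csv",
            "covariates": outdir / "covariates.csv",
            "windows": outdir / "windows.csv",
            "truth": outdir / "truth.json",
        }
        ev = self.events.copy()
        ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        ev.to_csv(paths["events"], index=False)
        self.covariates.to_csv(paths["covariates"], index=False)
        self.windows.to_csv(paths["windows"], index=False)
        if self.intervals is not None:
            paths["intervals"] = outdir / "covariate_intervals.csv"
            self.intervals.to_csv(paths["intervals"], index=False)
        truth = {
            "params": {
                "theta1": self.spec.true_params.theta1,
                "theta2": self.spec.true_params.theta2,
                "beta01": self.spec.true_params.beta01,
                "beta10": self.spec.true_params.beta10,
                "omega_sq": list(self.spec.true_params.omega_sq),
                "random_effects": self.spec.true_params.random_effects,
            },
            "eta_p01": list(map(float, self.truth["eta_p01"])),
            "eta_p10": list(map(float, self.truth["eta_p10"])),
            "subject_ids": list(self.truth["subject_ids"]),
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2)
        return paths


def _subject_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"S{i:0{width}d}" for i in range(1, n + 1)])


def generate_covariates(spec: CohortSpec,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Independent per-subject draws from the configured prevalences."""
    n = spec.n_subjects
    cols: dict[str, np.ndarray] = {"subject_id": _subject_ids(n)}
    for name, p in spec.prevalences.items():
        cols[name] = (rng.random(n) < p).astype(np.int8)
    for name, levels in spec.multinomials.items():
        lv = list(levels)
        draw = rng.choice(len(lv), size=n, p=list(levels.values()))
        for i, lvl in enumerate(lv):
            if i:
                cols[lvl] = (draw == i).astype(np.int8)
    return pd.DataFrame(cols)


def _daily_logits(spec: CohortSpec, cov: pd.DataFrame):
    """Per-subject linear predictors of the two logits (constant covariates)."""
    p = spec.true_params
    n = spec.n_subjects
    l1 = np.full(n, p.theta1)
    l2 = np.full(n, p.theta2)
    for name, b in p.beta01.items():
        if name in cov.columns:
            l1 = l1 + b * cov[name].to_numpy(dtype=float)
    for name, b in p.beta10.items():
        if name in cov.columns:
            l2 = l2 + b * cov[name].to_numpy(dtype=float)
    return l1[:, None], l2[:, None]              # broadcastable over days


def _simulate_states(l1: np.ndarray, l2: np.ndarray, eta1, eta2, n_days: int,
                     initial_state: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized chain simulation; l1/l2 broadcast to (n_subjects, n_days)."""
    n = len(eta1)
    p01 = expit(np.broadcast_to(l1, (n, n_days)) + eta1[:, None])
    p11 = 1.0 - expit(np.broadcast_to(l2, (n, n_days)) + eta2[:, None])
    u = rng.random((n, n_days))
    states = np.empty((n, n_days), dtype=np.int8)
    cur = np.full(n, initial_state, dtype=np.int8)
    for t in range(n_days):
        pnext = np.where(cur == 1, p11[:, t], p01[:, t])
        cur = (u[:, t] < pnext).astype(np.int8)
        states[:, t] = cur
    return states


def _events_from_states(spec: CohortSpec, ids: np.ndarray, states: np.ndarray,
                        rng: np.random.Generator) -> pd.DataFrame:
    subj_idx, day_idx = np.nonzero(states)
    lo, hi = spec.dose_window
    hours = rng.uniform(lo, hi, size=len(subj_idx))
    ts = (pd.Timestamp(spec.start_date)
          + pd.to_timedelta(day_idx, unit="D")
          + pd.to_timedelta(np.round(hours * 3600).astype(int), unit="s"))
    ev = pd.DataFrame({"subject_id": ids[subj_idx], "timestamp": ts})
    return ev.sort_values(["subject_id", "timestamp"], ignore_index=True)


def _windows_frame(spec: CohortSpec, ids: np.ndarray) -> pd.DataFrame:
    end = spec.start_date + timedelta(days=spec.n_days - 1)
    return pd.DataFrame({
        "subject_id": ids,
        "start_date": spec.start_date.isoformat(),
        "end_date": end.isoformat(),
    })


def generate_cohort(spec: CohortSpec | None = None, *,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> SyntheticCohort:
    """Draw a full cohort: covariates, random effects, chains, event log.

    Per subject, eta is drawn from N(0, omega^2) for each logit, daily
    transition probabilities follow from the true parameters and covariates,
    the chain starts in the configured initial state, and each dose-taking
    day emits one opening timestamp jittered inside the daily dose window.
    """
    spec = CohortSpec() if spec is None else spec
    if rng is None:
        rng = np.random.default_rng(seed)
    ids = _subject_ids(spec.n_subjects)
    cov = generate_covariates(spec, rng)
    sd1, sd2 = (math.sqrt(w) for w in spec.true_params.omega_sq)
    eta1 = rng.normal(0.0, sd1, spec.n_subjects)
    eta2 = rng.normal(0.0, sd2, spec.n_subjects)
    l1, l2 = _daily_logits(spec, cov)
    states = _simulate_states(l1, l2, eta1, eta2, spec.n_days,
                              spec.initial_state, rng)
    events = _events_from_states(spec, ids, states, rng)
    return SyntheticCohort(
        spec=spec,
        events=events,
        covariates=cov,
        windows=_windows_frame(spec, ids),
        intervals=None,
        truth={"subject_ids": list(ids), "eta_p01": eta1, "eta_p10": eta2,
               "states": states},
    )


def inject_timevarying(
    spec: CohortSpec,
    cohort: SyntheticCohort,
    *,
    art_switch_days: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Make follow-up and partner-ART indicators time-varying and re-simulate.

    The follow-up indicator switches 0 -> 1 for every subject at
    ``spec.followup_switch_day`` (1-based study day; default 183).  Subjects
    whose drawn ``partner_art_6m`` value is 1 switch at a per-subject day
    (supplied, or drawn uniformly over the window); subjects drawn 0 stay 0.
    The chain is re-simulated with day-specific probabilities using the
    cohort's existing random effects, and the covariate table is re-emitted
    in long interval format for the two time-varying columns.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n, n_days = spec.n_subjects, spec.n_days
    switch_fu = spec.followup_switch_day
    if not 1 <= switch_fu <= n_days:
        raise ConfigurationError(
            f"followup_switch_day {switch_fu} outside window 1..{n_days}")
    cov = cohort.covariates
    ids = np.asarray(cov["subject_id"])
    has_art = "partner_art_6m" in cov.columns
    if art_switch_days is None:
        if has_art:
            art_final = cov["partner_art_6m"].to_numpy(dtype=int)
            art_switch_days = np.where(
                art_final == 1, rng.integers(1, n_days + 1, size=n), n_days + 1)
        else:
            art_switch_days = np.full(n, n_days + 1)    # never on ART >= 6 mo
    art_switch_days = np.asarray(art_switch_days)
    if ((art_switch_days < 1) | (art_switch_days > n_days + 1)).any():
        raise ConfigurationError("ART switch day outside window")

    day = np.arange(1, n_days + 1)
    fu = (day >= switch_fu).astype(float)[None, :].repeat(n, axis=0)
    art = (day[None, :] >= art_switch_days[:, None]).astype(float)

    p = spec.true_params
    const = {c: cov[c].to_numpy(dtype=float)[:, None]
             for c in cov.columns if c not in
             ("subject_id", "followup_6m", "partner_art_6m")}
    varying = {"followup_6m": fu, "partner_art_6m": art}

    def lin(theta, beta):
        out = np.full((n, n_days), theta)
        for name, b in beta.items():
            if name in varying:
                out = out + b * varying[name]
            elif name in const:
                out = out + b * const[name]
        return out

    eta1 = np.asarray(cohort.truth["eta_p01"])
    eta2 = np.asarray(cohort.truth["eta_p10"])
    states = _simulate_states(lin(p.theta1, p.beta01), lin(p.theta2, p.beta10),
                              eta1, eta2, n_days, spec.initial_state, rng)
    events = _events_from_states(spec, ids, states, rng)

    rows = []
    for i, sid in enumerate(ids):
        varying_plan = [("followup_6m", switch_fu)]
        if has_art:
            varying_plan.append(("partner_art_6m", int(art_switch_days[i])))
        for covn, swday in varying_plan:
            if swday <= 1:
                rows.append((sid, covn, 1, 1, n_days))
            elif swday > n_days:
                rows.append((sid, covn, 0, 1, n_days))
            else:
                rows.append((sid, covn, 0, 1, swday - 1))
                rows.append((sid, covn, 1, swday, n_days))
    intervals = pd.DataFrame(rows, columns=[
        "subject_id", "covariate", "value",
        "interval_start_day", "interval_end_day"])

    constant = cov.drop(columns=[c for c in ("followup_6m", "partner_art_6m")
                                 if c in cov.columns])
    truth = dict(cohort.truth)
    truth["states"] = states
    truth["art_switch_days"] = art_switch_days
    return SyntheticCohort(
        spec=spec,
        events=events,
        covariates=constant,
        windows=_windows_frame(spec, ids),
        intervals=intervals,
        truth=truth,
    )
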