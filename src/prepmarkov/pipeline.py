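"""File-to-likelihood plumbing: load the three input files into a dataset."""

from __future__ import annotations

from . import io_events
from .io_events import DEFAULT_MAX_DAYS
from .transitions import TransitionDataset


def load_dataset(
    events_path,
    windows_path,
    covariates_path=None,
    intervals_path=None,
    *,
    max_days: int | None = DEFAULT_MAX_DAYS,
    initial_state: int = 1,
    delimiter: str = ",",
) -> TransitionDataset:
    """Event log + window file (+ covariate tables) -> TransitionDataset.

    Applies the standard reduction: daily binary states per window (truncated
    to ``max_days``), per-day covariate resolution, and first-order transition
    records with the configured day-1 previous state.
    """
    events = io_events.read_event_log(events_path, delimiter=delimiter)
    windows = io_events.read_window_file(windows_path, delimiter=delimiter)
    series = io_events.build_series(events, windows, max_days=max_days)
    cov_frames = None
    if covariates_path is not None:
        table = io_events.read_covariate_table(
            covariates_path, interval_path=intervals_path, delimiter=delimiter)
        cov_frames = [io_events.resolve_covariates(table, s) for s in series]
    return TransitionDataset.from_series(series, cov_frames,
                                         initial_state=initial_state)
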