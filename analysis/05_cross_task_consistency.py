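#!/usr/bin/env python
"""Cross-task consistency of individual learning.

Correlates subjects' learning-curve slopes across the two tasks (Pearson,
finite slopes only) and the inter-task interval in days against overall
reversal accuracy (Spearman).  Under the default synthetic cohort the two
tasks are generated independently, so both correlations should hover near
zero — the benchmark for claims that the tasks tap distinct processes.
"""

import pathlib
import warnings

from revlearn.classify_report import (
    cross_task_slope_correlation,
    inter_task_intervals,
    interval_performance_correlation,
)
from revlearn.learning_curves import fit_learning_curve
from revlearn.trial_data import read_trials_csv

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    _, sequences = read_trials_csv(OUT / "cohort.csv", strict=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        al = {s.subject_id: fit_learning_curve(s) for s in sequences if s.task == "AL"}
        rl = {s.subject_id: fit_learning_curve(s) for s in sequences if s.task == "RL"}
        r, p, n = cross_task_slope_correlation(al, rl)
    print(f"slope consistency across tasks: Pearson r = {r:+.2f}, "
          f"p = {p:.2f} ({n} paired subjects with finite slopes)")

    intervals = inter_task_intervals(sequences)
    rl_acc = {s.subject_id: s.proportion_correct
              for s in sequences if s.task == "RL"}
    shared = sorted(intervals.keys() & rl_acc.keys())
    rho, p2 = interval_performance_correlation(
        [intervals[s] for s in shared], [rl_acc[s] for s in shared],
    )
    print(f"inter-task interval vs reversal accuracy: Spearman rho = {rho:+.2f}, "
          f"p = {p2:.2f} ({len(shared)} subjects; "
          f"intervals {min(intervals.values())}-{max(intervals.values())} days)")


if __name__ == "__main__":
    main()
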