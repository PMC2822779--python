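"""Group-level statistics and the experiment-matrix runner.

Reproduces the reporting structure of a per-condition swimming study:
mean ± SEM left-side frequency, circular mean ± SEM contralateral phase over
the animals whose phase is defined, the proportion of animals with a defined
phase, and Student's paired/unpaired comparisons between conditions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .rhythm import RhythmSummary, analyze_trace
from .synth import preset, simulate_cohort

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "summarize_group",
    "students_t",
    "circular_mean",
    "circular_sd",
    "run_experiment_matrix",
    "ExperimentResult",
]


@dataclass
class GroupSummary:
    """Per-condition cohort summary (frequencies in Hz, phases in cycles)."""

    condition: str
    n: int
    freq_mean: float | None
    freq_sem: float | None
    phase_mean: float | None
    phase_sem: float | None
    prop_phase_defined: float
    alternation_mean: float | None
    single_animal: bool = False     # SEM is 0 by convention, flagged

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n": self.n,
            "freq_mean": self.freq_mean,
            "freq_sem": self.freq_sem,
            "phase_mean": self.phase_mean,
            "phase_sem": self.phase_sem,
            "prop_phase_defined": self.prop_phase_defined,
            "alternation_mean": self.alternation_mean,
        }


@dataclass
class GroupComparison:
    """Student's t comparison between two groups of per-animal values."""

    condition_a: str
    condition_b: str
    statistic: float
    p_value: float
    paired: bool
    df: float
    degenerate: bool = False        # zero-variance input; t undefined

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "paired": self.paired,
            "df": self.df,
            "degenerate": self.degenerate,
        }


# ---------------------------------------------------------------------------
# circular helpers (phases live on the unit circle, in cycles)
# ---------------------------------------------------------------------------
def circular_mean(phases) -> float:
    """Resultant-vector mean of phases in cycles, in [0, 1)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ParameterError("circular_mean: empty input")
    return float(stats.circmean(phases, high=1.0, low=0.0))


def circular_sd(phases) -> float:
    """Circular standard deviation of phases in cycles."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ParameterError("circular_sd: empty input")
    return float(stats.circstd(phases, high=1.0, low=0.0))


def summarize_group(
    summaries: list[RhythmSummary], condition: str | None = None
) -> GroupSummary:
    """Aggregate per-animal rhythm summaries into a group report.

    Frequency uses the arithmetic mean and SEM (SD/sqrt(n)) over animals with
    a defined period.  Phase uses the circular mean and circular SEM over
    animals with a defined phase, and is reported only when at least half the
    group has a defined phase.  A single-animal group gets SEM 0 by
    convention and is flagged.
    """
    if not summaries:
        raise ParameterError("summarize_group: empty input")
    if condition is None:
        condition = summaries[0].condition
    n = len(summaries)
    freqs = [s.frequency_hz for s in summaries if s.frequency_hz is not None]
    phases = [s.phase for s in summaries if s.phase_defined and s.phase is not None]
    alts = [s.alternation_index for s in summaries
            if s.alternation_index is not None]

    def mean_sem(values: list[float]) -> tuple[float | None, float | None]:
        if not values:
            return None, None
        if len(values) == 1:
            return float(values[0]), 0.0
        return float(np.mean(values)), float(np.std(values, ddof=1) / np.sqrt(len(values)))

    freq_mean, freq_sem = mean_sem(freqs)
    prop = len(phases) / n
    if phases and prop >= 0.5:
        phase_mean = circular_mean(phases)
        phase_sem = 0.0 if len(phases) == 1 else circular_sd(phases) / np.sqrt(len(phases))
    else:
        phase_mean = phase_sem = None
    alt_mean = float(np.mean(alts)) if alts else None
    return GroupSummary(
        condition=condition, n=n,
        freq_mean=freq_mean, freq_sem=freq_sem,
        phase_mean=phase_mean, phase_sem=phase_sem,
        prop_phase_defined=prop, alternation_mean=alt_mean,
        single_animal=(n == 1),
    )


def students_t(
    a, b, paired: bool = False, welch: bool = False,
    label_a: str = "a", label_b: str = "b",
) -> GroupComparison:
    """Classical Student's t test, two-sided.

    Unpaired uses the pooled-variance form by default (``welch=True``
    switches to the unequal-variance form).  Zero-variance inputs (e.g. a
    constant paired difference) are flagged degenerate rather than reported
    as an infinite t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and len(a) != len(b):
        raise ParameterError("students_t: paired test needs equal lengths")
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("students_t: each group needs n >= 2")
    if paired:
        diff = a - b
        df = float(len(diff) - 1)
        if np.allclose(diff, diff[0]):
            return GroupComparison(label_a, label_b, float("nan"), float("nan"),
                                   paired=True, df=df, degenerate=True)
        res = stats.ttest_rel(a, b)
        return GroupComparison(label_a, label_b, float(res.statistic),
                               float(res.pvalue), paired=True, df=df)
    if np.std(a) == 0 and np.std(b) == 0:
        df = float(len(a) + len(b) - 2)
        return GroupComparison(label_a, label_b, float("nan"), float("nan"),
                               paired=False, df=df, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    return GroupComparison(label_a, label_b, float(res.statistic),
                           float(res.pvalue), paired=False, df=df)


# ---------------------------------------------------------------------------
# experiment matrix
# ---------------------------------------------------------------------------
@dataclass
class ExperimentResult:
    """Output of :func:`run_experiment_matrix`."""

    table: pd.DataFrame                     # one row per condition
    per_animal: pd.DataFrame                # one row per simulated animal
    comparisons: list[GroupComparison] = field(default_factory=list)


def run_experiment_matrix(config: dict) -> ExperimentResult:
    """Simulate and analyze a whole experiment from a config mapping.

    Config keys:

    - ``conditions``: list of ``{"name": preset-name, "n": animals}``
      (optionally ``"overrides"`` patching any simulator parameter)
    - ``base_seed``: master seed; condition ``k`` uses trace seeds
      ``base_seed + 10000*k ...`` and surrogate seeds offset from them
    - ``comparisons``: optional list of ``{"a": name, "b": name,
      "paired": bool}`` t tests on left-side frequency
    - ``duration_s``, ``surrogates``, ``alpha``: optional analysis settings

    Fully reproducible: identical config and seed give identical tables.
    """
    conditions = config.get("conditions", [])
    if not conditions:
        raise ParameterError("experiment config: empty condition list")
    base_seed = int(config.get("base_seed", 0))
    duration_s = config.get("duration_s")
    n_surrogates = int(config.get("surrogates", 199))
    alpha = float(config.get("alpha", 0.05))

    groups: dict[str, GroupSummary] = {}
    freq_by_condition: dict[str, list[float]] = {}
    animal_rows = []
    for k, spec_ in enumerate(conditions):
        name = spec_["name"]
        n = int(spec_["n"])
        overrides = dict(spec_.get("overrides", {}))
        if duration_s is not None:
            overrides.setdefault("duration_s", float(duration_s))
        cond = preset(name)     # raises UnknownConditionError early
        traces = simulate_cohort(cond, n, base_seed=base_seed + 10000 * k,
                                 **overrides)
        summaries = []
        for i, tr in enumerate(traces):
            s = analyze_trace(tr, n_surrogates=n_surrogates, alpha=alpha,
                              seed=base_seed + 10000 * k + 5000 + i)
            summaries.append(s)
            row = s.to_dict()
            row["seed"] = tr.seed
            row.pop("notes")
            animal_rows.append(row)
        groups[name] = summarize_group(summaries, condition=name)
        freq_by_condition[name] = [
            s.frequency_hz for s in summaries if s.frequency_hz is not None]

    comparisons = []
    for cmp_ in config.get("comparisons", []):
        a, b = cmp_["a"], cmp_["b"]
        for label in (a, b):
            if label not in freq_by_condition:
                raise ParameterError(
                    f"comparison references unknown condition {label!r}")
        comparisons.append(students_t(
            freq_by_condition[a], freq_by_condition[b],
            paired=bool(cmp_.get("paired", False)),
            welch=bool(cmp_.get("welch", False)),
            label_a=a, label_b=b,
        ))

    table = pd.DataFrame([g.to_dict() for g in groups.values()])
    per_animal = pd.DataFrame(animal_rows)
    return ExperimentResult(table=table, per_animal=per_animal,
                            comparisons=comparisons)
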