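"""Connectivity-state trial splits and MEP modulation statistics.

Trials are divided per cROI at the median of the per-trial iPLV into
high-connectivity (HC) and low-connectivity (LC) sets; network-level sets
(HC_network / LC_network) are the trials that are simultaneously HC (or LC)
for every cROI.  MEP modulation of a subset S is expressed per subject as
the percent change of its mean amplitude relative to the subject's overall
mean, and HC-vs-LC differences are tested across subjects with a one-tailed
paired t-test (directional hypothesis: high connectivity facilitates MEPs).
Control splits (first/second half, even/odd) use two-tailed tests on median
amplitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TrialSplit:
    hc: dict[str, np.ndarray]
    lc: dict[str, np.ndarray]
    hc_network: np.ndarray
    lc_network: np.ndarray
    overlap_percent: float


@dataclass
class ModulationResult:
    mod_a: np.ndarray            # per-subject percent modulation, subset A
    mod_b: np.ndarray
    mean_diff: float
    sem_diff: float
    t: float | None
    p: float | None
    n_subjects: int
    note: str = ""


def median_split(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split trial indices at the median of ``values``.

    Values strictly above the median go to HC, strictly below to LC.  Values
    equal to the median are assigned deterministically so the two sets stay
    balanced: each tie goes to the currently smaller set, alternating
    (starting with HC) when the sets are equal.  Guarantees
    ``| |HC| − |LC| | ≤ 1``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10 or np.any(~np.isfinite(values)):
        raise ValueError("need at least 10 finite values")
    med = float(np.median(values))
    hc = list(np.flatnonzero(values > med))
    lc = list(np.flatnonzero(values < med))
    ties = np.flatnonzero(values == med)
    if len(ties) == len(values):
        raise ValueError("degenerate connectivity: all values identical")
    toggle_hc = True
    for t in ties:
        if len(hc) < len(lc):
            hc.append(t)
        elif len(lc) < len(hc):
            lc.append(t)
        else:
            (hc if toggle_hc else lc).append(t)
            toggle_hc = not toggle_hc
    return np.sort(hc).astype(int), np.sort(lc).astype(int)


def network_trials(splits: dict[str, tuple[np.ndarray, np.ndarray]]) -> TrialSplit:
    """Intersect per-cROI splits into network-level HC/LC sets.

    ``splits`` maps cROI name to its (hc_indices, lc_indices).  For the
    two-cROI case the overlap percentage 100·|HC₁∩HC₂|/|HC₁| is reported.
    """
    if not splits:
        raise ValueError("need at least one cROI split")
    names = list(splits)
    hc_sets = [set(splits[n][0].tolist()) for n in names]
    lc_sets = [set(splits[n][1].tolist()) for n in names]
    hc_net = set.intersection(*hc_sets)
    lc_net = set.intersection(*lc_sets)
    if not hc_net or not lc_net:
        warnings.warn("empty network-level trial set", stacklevel=2)
    overlap = float("nan")
    if len(names) == 2 and hc_sets[0]:
        overlap = 100.0 * len(hc_sets[0] & hc_sets[1]) / len(hc_sets[0])
    return TrialSplit(
        hc={n: splits[n][0] for n in names},
        lc={n: splits[n][1] for n in names},
        hc_network=np.array(sorted(hc_net), dtype=int),
        lc_network=np.array(sorted(lc_net), dtype=int),
        overlap_percent=overlap)


def _percent_modulation(mep: np.ndarray, subset: np.ndarray) -> float:
    """Percent change of the subset mean relative to the overall mean MEP."""
    overall = float(np.mean(mep))
    return 100.0 * (float(np.mean(mep[subset])) - overall) / overall


def modulation(meps_by_subject: list[np.ndarray],
               subset_a: list[np.ndarray],
               subset_b: list[np.ndarray],
               alternative: str = "greater") -> ModulationResult:
    """Per-subject percent MEP modulation for two trial subsets and group test.

    ``meps_by_subject`` holds each subject's per-trial linear MEP amplitudes
    (mV); subsets are per-subject index arrays.  The group test is a paired
    t-test across subjects on mod(A) − mod(B), one-tailed A > B by default.
    Requires at least 3 subjects for the test (skipped with a notice below).
    """
    n_sub = len(meps_by_subject)
    if not (len(subset_a) == len(subset_b) == n_sub):
        raise ValueError("per-subject inputs must align")
    mod_a = np.empty(n_sub)
    mod_b = np.empty(n_sub)
    for i, mep in enumerate(meps_by_subject):
        mep = np.asarray(mep, dtype=float)
        if len(subset_a[i]) == 0 or len(subset_b[i]) == 0:
            raise ValueError(f"empty subset for subject {i}")
        mod_a[i] = _percent_modulation(mep, np.asarray(subset_a[i], dtype=int))
        mod_b[i] = _percent_modulation(mep, np.asarray(subset_b[i], dtype=int))
    diff = mod_a - mod_b
    sem = float(stats.sem(diff)) if n_sub > 1 else float("nan")
    if n_sub < 3:
        return ModulationResult(mod_a, mod_b, float(diff.mean()), sem,
                                None, None, n_sub,
                                note="fewer than 3 subjects: group test skipped")
    if np.allclose(diff, diff[0]):
        # identical differences (e.g. A == B): no variance, define p by direction
        p = 0.5 if np.isclose(diff[0], 0) else (0.0 if diff[0] > 0 else 1.0)
        return ModulationResult(mod_a, mod_b, float(diff.mean()), sem,
                                float("inf") if diff[0] else 0.0, p, n_sub)
    t, p = stats.ttest_rel(mod_a, mod_b, alternative=alternative)
    return ModulationResult(mod_a, mod_b, float(diff.mean()), sem,
                            float(t), float(p), n_sub)


def control_splits(n_trials: int) -> tuple[tuple[np.ndarray, np.ndarray],
                                           tuple[np.ndarray, np.ndarray]]:
    """Connectivity-agnostic control splits: (first, second) halves and (even, odd)."""
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    idx = np.arange(n_trials)
    half = n_trials // 2
    return (idx[:half], idx[half:]), (idx[::2], idx[1::2])


def control_split_tests(meps_by_subject: list[np.ndarray]) -> dict[str, dict]:
    """Two-tailed paired t-tests on per-subject median MEPs for both controls."""
    res: dict[str, dict] = {}
    for name, pick in (("first_vs_second", 0), ("even_vs_odd", 1)):
        med_a, med_b = [], []
        for mep in meps_by_subject:
            mep = np.asarray(mep, dtype=float)
            a, b = control_splits(len(mep))[pick]
            med_a.append(float(np.median(mep[a])))
            med_b.append(float(np.median(mep[b])))
        t, p = stats.ttest_rel(med_a, med_b)
        res[name] = {"t": float(t), "p": float(p),
                     "median_a": med_a, "median_b": med_b}
    return res
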