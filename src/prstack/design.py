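"""Age/sex-matched case-control design with a 70/30 split.

Cases (incident only; prevalent cases must be excluded upstream) define five
age bins by their age quintiles; crossed with sex this gives ten strata.
Within each stratum every case receives k matched controls, with k the
largest value in {5, ..., 1} every stratum can supply; 70% of the matched
sets (case plus its controls, as a unit, stratified by stratum) form the
training set. The testing set takes the remaining 30% of cases plus 5
unmatched controls per case drawn from unaffected individuals not used in
training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rng import substream

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """The cohort cannot support the requested matched design."""


@dataclass
class StratumSpec:
    """Age-quintile cut points and the (age bin, sex) -> stratum id map."""

    cuts: np.ndarray          # ascending interior cut points (usually 4)
    sexes: tuple[str, ...] = ("female", "male")
    degenerate: bool = False  # all case ages identical -> sex-only strata

    @property
    def n_age_bins(self) -> int:
        return 1 if self.degenerate else len(self.cuts) + 1

    @property
    def n_strata(self) -> int:
        return self.n_age_bins * len(self.sexes)

    def assign(self, ages, sexes) -> np.ndarray:
        """Stratum id (1-based) per individual; ages outside the case range
        fall into the nearest extreme bin."""
        ages = np.asarray(ages)
        sex_idx = np.asarray([self.sexes.index(s) for s in sexes])
        if self.degenerate:
            age_bin = np.zeros(len(ages), dtype=np.int64)
        else:
            # bins left-closed, right-open except the last (searchsorted
            # 'right' puts age == cut into the next bin)
            age_bin = np.searchsorted(self.cuts, ages, side="right")
        return age_bin * len(self.sexes) + sex_idx + 1


def age_strata(case_ages, sexes: tuple[str, ...] = ("female", "male")
               ) -> StratumSpec:
    """Five age bins from the 20/40/60/80th percentiles of case ages
    (linear-interpolation quantiles), crossed with sex.

    With fewer than two distinct case ages the age dimension collapses and
    only sex strata remain (a warning is emitted).
    """
    case_ages = np.asarray(case_ages, dtype=np.float64)
    case_ages = case_ages[~np.isnan(case_ages)]
    if case_ages.size < 5:
        raise DesignError("need at least 5 cases with non-missing age")
    cuts = np.quantile(case_ages, [0.2, 0.4, 0.6, 0.8])
    if np.unique(case_ages).size == 1 or np.unique(cuts).size < len(cuts):
        if np.unique(case_ages).size == 1:
            warnings.warn(
                "all case ages identical; falling back to sex-only strata"
            )
            return StratumSpec(cuts=np.array([]), sexes=sexes, degenerate=True)
        # tied quantiles: merge identical cut points, keep remaining bins
        cuts = np.unique(cuts)
    return StratumSpec(cuts=cuts, sexes=sexes)


@dataclass
class MatchedDesign:
    """Matched sets plus train/test membership.

    matched_sets maps case id -> list of matched control ids; train_sets is
    the subset of case ids whose sets form the training data.
    """

    strata: StratumSpec
    k: int
    matched_sets: dict[str, list[str]]
    stratum_of_case: dict[str, int]
    train_sets: list[str]
    test_cases: list[str] = field(default_factory=list)
    test_controls: list[str] = field(default_factory=list)
    shortfall: dict[int, int] = field(default_factory=dict)

    @property
    def train_ids(self) -> list[str]:
        ids: list[str] = []
        for case in self.train_sets:
            ids.append(case)
            ids.extend(self.matched_sets[case])
        return ids

    @property
    def test_ids(self) -> list[str]:
        return list(self.test_cases) + list(self.test_controls)

    def summary(self) -> pd.DataFrame:
        """Per-stratum case and control counts of the full matched design."""
        rows = []
        for sid in range(1, self.strata.n_strata + 1):
            cases = [c for c, s in self.stratum_of_case.items() if s == sid]
            n_controls = sum(len(self.matched_sets[c]) for c in cases)
            rows.append({"stratum": sid, "n_cases": len(cases),
                         "n_controls": n_controls,
                         "shortfall": self.shortfall.get(sid, 0)})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        train = set(self.train_sets)
        for case, controls in self.matched_sets.items():
            split = "train" if case in train else "test"
            sid = self.stratum_of_case[case]
            rows.append({"id": case, "role": "case", "split": split,
                         "stratum": sid, "set_id": case})
            if split == "train":
                for ctrl in controls:
                    rows.append({"id": ctrl, "role": "control",
                                 "split": "train", "stratum": sid,
                                 "set_id": case})
        for ctrl in self.test_controls:
            rows.append({"id": ctrl, "role": "control", "split": "test",
                         "stratum": 0, "set_id": ""})
        return pd.DataFrame(rows)


def _eligible(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Incident cases and unaffected controls; prevalent cases are excluded
    from both pools."""
    is_case = cohort["status"] == "case"
    incident = cohort["incident"].astype("Int64").fillna(0) == 1
    cases = cohort[is_case & incident]
    controls = cohort[~is_case]
    return cases, controls


def sample_matched_training(cohort: pd.DataFrame, strata: StratumSpec,
                            k_max: int = 5, split: float = 0.70,
                            seed: int = 0) -> MatchedDesign:
    """Draw k matched controls per incident case and split sets 70/30.

    k is the largest value <= k_max that every stratum can supply; when even
    k = 1 is infeasible somewhere, the k with minimal total shortfall is
    used and deficient strata contribute all their controls. The train/test
    split operates on whole matched sets, stratified by stratum.
    """
    rng = substream(seed, "design")
    cases, controls = _eligible(cohort)
    if cases.empty:
        raise DesignError("no eligible (incident) cases in cohort")
    case_sid = strata.assign(cases["age"].to_numpy(), cases["sex"].to_numpy())
    ctrl_sid = strata.assign(controls["age"].to_numpy(),
                             controls["sex"].to_numpy())

    case_ids_by_s = {s: cases["id"].to_numpy()[case_sid == s]
                     for s in range(1, strata.n_strata + 1)}
    ctrl_ids_by_s = {s: controls["id"].to_numpy()[ctrl_sid == s]
                     for s in range(1, strata.n_strata + 1)}
    for s, cs in case_ids_by_s.items():
        if len(cs) > 0 and len(ctrl_ids_by_s[s]) == 0:
            raise DesignError(f"stratum {s} has {len(cs)} cases but no controls")

    def total_shortfall(k: int) -> int:
        return sum(
            max(0, k * len(case_ids_by_s[s]) - len(ctrl_ids_by_s[s]))
            for s in case_ids_by_s
        )

    k = next((kk for kk in range(k_max, 0, -1) if total_shortfall(kk) == 0), None)
    if k is None:
        best = min(total_shortfall(kk) for kk in range(1, k_max + 1))
        k = max(kk for kk in range(1, k_max + 1) if total_shortfall(kk) == best)
        logger.warning("matched design short by %d controls at k=%d", best, k)

    matched_sets: dict[str, list[str]] = {}
    stratum_of_case: dict[str, int] = {}
    shortfall: dict[int, int] = {}
    for s in sorted(case_ids_by_s):
        cs = case_ids_by_s[s]
        if len(cs) == 0:
            continue
        pool = ctrl_ids_by_s[s]
        need = k * len(cs)
        if need <= len(pool):
            drawn = rng.choice(pool, size=need, replace=False)
        else:
            drawn = rng.permutation(pool)
            shortfall[s] = need - len(pool)
        # deal controls to cases round-robin so deficits spread evenly
        for j, case in enumerate(cs):
            matched_sets[str(case)] = [str(c) for c in drawn[j::len(cs)][:k]]
            stratum_of_case[str(case)] = int(s)

    train_sets: list[str] = []
    for s in sorted(case_ids_by_s):
        cs = [str(c) for c in case_ids_by_s[s]]
        if not cs:
            continue
        n_train = int(round(split * len(cs)))
        chosen = rng.choice(len(cs), size=n_train, replace=False)
        train_sets.extend(cs[i] for i in sorted(chosen))

    return MatchedDesign(
        strata=strata, k=k, matched_sets=matched_sets,
        stratum_of_case=stratum_of_case, train_sets=train_sets,
        shortfall=shortfall,
    )


def build_test_set(cohort: pd.DataFrame, design: MatchedDesign,
                   ratio: int = 5, seed: int = 0) -> MatchedDesign:
    """Fill the testing side: held-out cases plus ratio unmatched controls
    per case, drawn from unaffected individuals untouched by training."""
    rng = substream(seed, "test_design")
    train = set(design.train_sets)
    design.test_cases = [c for c in design.matched_sets if c not in train]

    used = set(design.train_ids)
    _, controls = _eligible(cohort)
    pool = np.array([c for c in controls["id"].astype(str) if c not in used])
    need = ratio * len(design.test_cases)
    if need > len(pool):
        logger.warning("test control pool short by %d", need - len(pool))
        need = len(pool)
    drawn = rng.choice(pool, size=need, replace=False)
    design.test_controls = [str(c) for c in drawn]

    overlap = used & set(design.test_ids)
    assert not overlap, f"train/test overlap: {sorted(overlap)[:5]}"
    return design
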