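"""Patient-level trial data: containers, severity classification, and estimators.

The trial is a three-phase add-on study of an oromucosal THC:CBD spray
(nabiximols / Sativex) added to standard spasticity care in multiple
sclerosis.  Each patient carries one spasticity NRS summary value per 28-day
model cycle (index ``c`` is the measurement at the *start* of cycle ``c``, so
the cycle-``c`` transition is the pair ``(c, c + 1)``) and, where available, a
concurrent health-state utility mapped from quality-of-life questionnaires.

Severity states follow the model's NRS cut-offs: mild below 3.3, moderate
from 3.3 to 6.6 inclusive, severe above 6.6.  Missing observations are never
imputed; a patient simply drops out of the at-risk count for the cycles and
rows they do not cover.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NRS_MILD_UPPER",
    "NRS_MODERATE_UPPER",
    "SeverityState",
    "Stratum",
    "PatientRecord",
    "TrialDataset",
    "TransitionEstimate",
    "UtilitySet",
    "EstimationError",
    "NoObservationsError",
    "classify_nrs",
    "classify_nrs_array",
    "estimate_transition_matrix",
    "estimate_utilities",
    "transitions_to_frame",
]

NRS_MILD_UPPER = 3.3
NRS_MODERATE_UPPER = 6.6


class SeverityState(enum.IntEnum):
    """Spasticity severity band of the 0-10 numerical rating scale."""

    MILD = 0
    MODERATE = 1
    SEVERE = 2


class Stratum(enum.IntEnum):
    """Bootstrap stratum, i.e. how far a patient progressed in the trial.

    ``SINGLE_BLIND_ONLY`` patients completed only the single-blind titration
    phase (non-responders) or failed the wash-out; ``DB_SATIVEX`` and
    ``DB_PLACEBO`` are the two randomised double-blind arms.
    """

    SINGLE_BLIND_ONLY = 0
    DB_SATIVEX = 1
    DB_PLACEBO = 2


class EstimationError(ValueError):
    """Raised when an estimator cannot produce a result from the data given."""


class NoObservationsError(EstimationError):
    """Raised when a requested cycle has no transition observations at all."""


def classify_nrs(score: float) -> SeverityState:
    """Map an NRS score in [0, 10] to its severity state.

    Mild is ``[0, 3.3)``, moderate the closed band ``[3.3, 6.6]`` and severe
    ``(6.6, 10]``, so every admissible score maps to exactly one state.
    """
    if not 0.0 <= score <= 10.0:
        raise ValueError(f"NRS score must lie in [0, 10], got {score!r}")
    if score < NRS_MILD_UPPER:
        return SeverityState.MILD
    if score <= NRS_MODERATE_UPPER:
        return SeverityState.MODERATE
    return SeverityState.SEVERE


def classify_nrs_array(scores: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_nrs`; NaN entries propagate as -1."""
    scores = np.asarray(scores, dtype=float)
    valid = ~np.isnan(scores)
    if np.any((scores[valid] < 0) | (scores[valid] > 10)):
        raise ValueError("NRS scores must lie in [0, 10]")
    out = np.full(scores.shape, -1, dtype=np.int8)
    out[valid & (scores < NRS_MILD_UPPER)] = SeverityState.MILD
    out[valid & (scores >= NRS_MILD_UPPER) & (scores <= NRS_MODERATE_UPPER)] = (
        SeverityState.MODERATE
    )
    out[valid & (scores > NRS_MODERATE_UPPER)] = SeverityState.SEVERE
    return out


@dataclass
class PatientRecord:
    """One patient's cycle-level observations.

    ``nrs_by_cycle[c]`` is the NRS summary at the start of cycle ``c``
    (1-based); a utility observation at ``c`` requires a concurrent NRS value,
    because utilities are attributed to the concurrent severity state.
    """

    patient_id: str
    stratum: Stratum
    nrs_by_cycle: dict[int, float] = field(default_factory=dict)
    utility_by_cycle: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stratum = Stratum(self.stratum)
        for c, v in self.nrs_by_cycle.items():
            if int(c) < 1:
                raise ValueError(f"cycle indices must be positive, got {c}")
            if not 0.0 <= v <= 10.0:
                raise ValueError(f"NRS {v} at cycle {c} outside [0, 10]")
        for c, v in self.utility_by_cycle.items():
            if c not in self.nrs_by_cycle:
                raise ValueError(
                    f"utility at cycle {c} has no concurrent NRS observation"
                )
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"utility {v} at cycle {c} outside [-1, 1]")


class TrialDataset:
    """Column-oriented container for a whole trial.

    Internally a dense ``(n_patients, n_timepoints)`` float matrix per signal
    with NaN for missing entries; column ``t`` holds the cycle ``t + 1``
    observation.  This layout keeps bootstrap resampling (row fancy-indexing)
    and transition counting cheap.
    """

    def __init__(
        self,
        patient_ids: Sequence[str],
        stratum: Sequence[int],
        nrs: np.ndarray,
        utility: np.ndarray,
    ) -> None:
        self.patient_ids = np.asarray(patient_ids, dtype=object)
        self.stratum = np.asarray(stratum, dtype=np.int8)
        self.nrs = np.asarray(nrs, dtype=float)
        self.utility = np.asarray(utility, dtype=float)
        if self.nrs.shape != self.utility.shape or self.nrs.ndim != 2:
            raise ValueError("nrs and utility must be equal-shape 2-D arrays")
        if len(self.patient_ids) != self.nrs.shape[0] or len(self.stratum) != len(
            self.patient_ids
        ):
            raise ValueError("patient_ids, stratum and data rows disagree")
        with np.errstate(invalid="ignore"):
            if np.any((self.nrs < 0) | (self.nrs > 10)):
                raise ValueError("NRS values outside [0, 10]")
            if np.any((self.utility < -1) | (self.utility > 1)):
                raise ValueError("utility values outside [-1, 1]")
        if np.any(~np.isnan(self.utility) & np.isnan(self.nrs)):
            raise ValueError("utility observation without concurrent NRS")

    # -- basic shape -------------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.nrs.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.nrs.shape[1]

    @property
    def counts_by_stratum(self) -> dict[Stratum, int]:
        return {s: int(np.sum(self.stratum == s)) for s in Stratum}

    def indices_of(self, strata: Iterable[Stratum]) -> np.ndarray:
        codes = [int(s) for s in strata]
        return np.flatnonzero(np.isin(self.stratum, codes))

    def subset(self, rows: np.ndarray) -> "TrialDataset":
        """Row-indexed view copy; repeated indices allowed (bootstrap)."""
        return TrialDataset(
            self.patient_ids[rows],
            self.stratum[rows],
            self.nrs[rows],
            self.utility[rows],
        )

    # -- construction / IO -------------------------------------------------
    @classmethod
    def from_patients(cls, patients: Iterable[PatientRecord]) -> "TrialDataset":
        patients = list(patients)
        if not patients:
            raise ValueError("cannot build a TrialDataset from zero patients")
        t_max = max((max(p.nrs_by_cycle, default=1) for p in patients), default=1)
        nrs = np.full((len(patients), t_max), np.nan)
        util = np.full((len(patients), t_max), np.nan)
        for i, p in enumerate(patients):
            for c, v in p.nrs_by_cycle.items():
                nrs[i, c - 1] = v
            for c, v in p.utility_by_cycle.items():
                util[i, c - 1] = v
        return cls(
            [p.patient_id for p in patients],
            [int(p.stratum) for p in patients],
            nrs,
            util,
        )

    def to_patients(self) -> list[PatientRecord]:
        out = []
        for i in range(self.n_patients):
            nrs = {
                t + 1: float(v)
                for t, v in enumerate(self.nrs[i])
                if not np.isnan(v)
            }
            util = {
                t + 1: float(v)
                for t, v in enumerate(self.utility[i])
                if not np.isnan(v)
            }
            out.append(
                PatientRecord(str(self.patient_ids[i]), Stratum(self.stratum[i]), nrs, util)
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per observed patient-cycle."""
        rows = []
        for i in range(self.n_patients):
            for t in range(self.n_timepoints):
                if np.isnan(self.nrs[i, t]):
                    continue
                u = self.utility[i, t]
                rows.append(
                    {
                        "patient_id": self.patient_ids[i],
                        "stratum": Stratum(self.stratum[i]).name,
                        "cycle": t + 1,
                        "nrs": self.nrs[i, t],
                        "utility": u if not np.isnan(u) else None,
                    }
                )
        return pd.DataFrame(rows, columns=["patient_id", "stratum", "cycle", "nrs", "utility"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TrialDataset":
        df = pd.read_csv(path, dtype={"patient_id": str})
        required = {"patient_id", "stratum", "cycle", "nrs"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
        if "utility" not in df.columns:
            df["utility"] = np.nan
        records: dict[str, PatientRecord] = {}
        for row in df.itertuples(index=False):
            rec = records.get(row.patient_id)
            if rec is None:
                rec = PatientRecord(row.patient_id, Stratum[row.stratum], {}, {})
                records[row.patient_id] = rec
            c = int(row.cycle)
            rec.nrs_by_cycle[c] = float(row.nrs)
            if row.utility is not None and not pd.isna(row.utility):
                rec.utility_by_cycle[c] = float(row.utility)
        return cls.from_patients(records.values())


@dataclass(frozen=True)
class TransitionEstimate:
    """A per-cycle 3x3 severity transition matrix with its supporting counts.

    The matrix is conditional on remaining on treatment and alive;
    discontinuation and death are layered on when the full model matrix is
    composed.  Rows with no at-risk patients are returned as identity rows
    and listed in ``identity_rows``.
    """

    cycle: int
    matrix: np.ndarray
    n_at_risk: int
    row_counts: np.ndarray
    identity_rows: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("transition probabilities outside [0, 1]")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1")


@dataclass(frozen=True)
class UtilitySet:
    """QALY weight (per year of occupancy) for each severity state."""

    u_mild: float
    u_moderate: float
    u_severe: float

    def __post_init__(self) -> None:
        for name, v in zip(("u_mild", "u_moderate", "u_severe"), self.as_array()):
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.u_mild, self.u_moderate, self.u_severe], dtype=float)


def estimate_transition_matrix(
    dataset: TrialDataset,
    cycle: int,
    arm_filter: Iterable[Stratum] | None = None,
    warn: bool = True,
) -> TransitionEstimate:
    """Row-wise maximum-likelihood transition matrix for one cycle.

    Entry ``(i, j)`` is the fraction of patients (restricted to
    ``arm_filter`` strata) observed in state ``i`` at the start of the cycle
    and state ``j`` at its end; patients missing either endpoint are excluded
    from that row.  Rows with zero at-risk patients fall back to the identity
    row (flagged and, when ``warn``, warned about) so that small bootstrap
    replicates still yield a usable schedule.
    """
    if dataset.n_patients == 0:
        raise EstimationError("empty dataset")
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    if arm_filter is None:
        rows = np.arange(dataset.n_patients)
    else:
        strata = list(arm_filter)
        if not strata:
            raise ValueError("arm_filter must be non-empty")
        rows = dataset.indices_of(strata)
    if cycle >= dataset.n_timepoints:
        raise NoObservationsError(
            f"cycle {cycle} requires observations at cycles {cycle} and {cycle + 1}; "
            f"dataset covers cycles 1..{dataset.n_timepoints}"
        )
    start = classify_nrs_array(dataset.nrs[rows, cycle - 1])
    end = classify_nrs_array(dataset.nrs[rows, cycle])
    ok = (start >= 0) & (end >= 0)
    if not np.any(ok):
        raise NoObservationsError(f"no transition observations at cycle {cycle}")
    counts = np.zeros((3, 3))
    np.add.at(counts, (start[ok], end[ok]), 1.0)
    row_counts = counts.sum(axis=1)
    matrix = np.eye(3)
    identity_rows = []
    for i in range(3):
        if row_counts[i] > 0:
            matrix[i] = counts[i] / row_counts[i]
        else:
            identity_rows.append(i)
    if identity_rows and warn:
        names = ", ".join(SeverityState(i).name for i in identity_rows)
        warnings.warn(
            f"cycle {cycle}: no at-risk patients in row(s) {names}; "
            "using identity row(s)",
            stacklevel=2,
        )
    return TransitionEstimate(
        cycle=cycle,
        matrix=matrix,
        n_at_risk=int(row_counts.sum()),
        row_counts=row_counts,
        identity_rows=tuple(identity_rows),
    )


def estimate_utilities(
    dataset: TrialDataset, fallback: UtilitySet | None = None
) -> UtilitySet:
    """Pooled mean utility per severity state.

    Every utility observation is attributed to the severity state of its
    concurrent NRS value and pooled over patients, cycles and strata.  A state
    with zero observations raises, unless a ``fallback`` set supplies its
    value (used inside bootstrap replicates, where a rare replicate can miss
    a state entirely).
    """
    if dataset.n_patients == 0:
        raise EstimationError("empty dataset")
    states = classify_nrs_array(dataset.nrs)
    has_u = ~np.isnan(dataset.utility)
    means = []
    for s in SeverityState:
        mask = has_u & (states == int(s))
        if not np.any(mask):
            if fallback is None:
                raise EstimationError(
                    f"no utility observations for state {s.name}"
                )
            means.append(float(fallback.as_array()[int(s)]))
        else:
            means.append(float(dataset.utility[mask].mean()))
    return UtilitySet(*means)


def transitions_to_frame(estimates: Iterable[TransitionEstimate]) -> pd.DataFrame:
    """Long-format export: cycle, from_state, to_state, probability."""
    rows = []
    for est in estimates:
        for i in SeverityState:
            for j in SeverityState:
                rows.append(
                    {
                        "cycle": est.cycle,
                        "from_state": i.name,
                        "to_state": j.name,
                        "probability": est.matrix[int(i), int(j)],
                    }
                )
    return pd.DataFrame(rows, columns=["cycle", "from_state", "to_state", "probability"])
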