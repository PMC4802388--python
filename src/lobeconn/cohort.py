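"""Domain containers for a longitudinal connectome cohort and their on-disk forms.

Everything is stored as plain TSV so a cohort directory is human-inspectable:

* ``parcellation.tsv`` — roi_id, name, hemisphere, module_id, partner
* ``subjects.tsv`` — one row per subject with outcome/laterality/demographics
* ``timeseries/<subject>_<session>.tsv`` — T rows x N columns, header = ROI names
* ``motion/<subject>_<session>.tsv`` — T x 6 rigid-body parameters
* ``nuisance/<subject>_<session>.tsv`` — T x 2 CSF/WM stand-in series
* ``lesions.tsv`` — long table (subject_id, roi_id, fraction) plus lacuna volumes
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PRE = "pre"
POST = "post"
SESSIONS = (PRE, POST)


@dataclass(frozen=True)
class Parcellation:
    """Node definition of the network: names, hemispheres, functional modules
    and the homotopic (mirror-image) partner of every region."""

    names: tuple[str, ...]
    hemisphere: np.ndarray  # array of 'L'/'R'
    module_id: np.ndarray   # int, 1-based
    partner: np.ndarray     # roi_id of the mirror ROI

    def __post_init__(self) -> None:
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("ROI names must be unique")
        for arr_name in ("hemisphere", "module_id", "partner"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length != number of ROIs")
        p = np.asarray(self.partner)
        if not np.array_equal(p[p], np.arange(n)):
            raise ValueError("homotopic partner map must be an involution")
        if np.any(self.hemisphere[p] == self.hemisphere):
            raise ValueError("homotopic partners must lie in opposite hemispheres")
        if np.any(self.module_id[p] != self.module_id):
            raise ValueError("homotopic partners must share a module")

    @property
    def n_rois(self) -> int:
        return len(self.names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": np.arange(self.n_rois),
                "name": list(self.names),
                "hemisphere": self.hemisphere,
                "module_id": self.module_id,
                "partner": self.partner,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Parcellation":
        df = df.sort_values("roi_id")
        return cls(
            names=tuple(df["name"]),
            hemisphere=df["hemisphere"].to_numpy(dtype="U1"),
            module_id=df["module_id"].to_numpy(dtype=int),
            partner=df["partner"].to_numpy(dtype=int),
        )


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    outcome: str            # "SF" | "NSF"
    laterality: str         # "L" | "R"
    sessions: tuple[str, ...]
    age_years: float
    sex: str                # "M" | "F"
    onset_age_years: float
    duration_years: float
    lacuna_volume_cm3: float | None = None

    def __post_init__(self) -> None:
        if self.outcome not in ("SF", "NSF"):
            raise ValueError(f"outcome must be SF or NSF, got {self.outcome!r}")
        if self.laterality not in ("L", "R"):
            raise ValueError(f"laterality must be L or R, got {self.laterality!r}")
        if not set(self.sessions) <= set(SESSIONS):
            raise ValueError(f"unknown session in {self.sessions}")
        if self.duration_years > self.age_years:
            raise ValueError("epilepsy duration cannot exceed age")
        if POST in self.sessions and self.lacuna_volume_cm3 is None:
            raise ValueError(f"{self.subject_id}: post session requires a lacuna volume")


@dataclass(frozen=True)
class RoiTimeSeries:
    """One session's T x N matrix of regional signals."""

    subject_id: str
    session: str
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("time series must be a T x N matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.data.shape[0] < 32:
            raise ValueError("need at least 32 time points for filtering headroom")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        return RoiTimeSeries(self.subject_id, self.session, data, self.tr_seconds)


@dataclass(frozen=True)
class LesionProfile:
    """Per-ROI damage fractions (0..1) left by the resection, plus cavity volume."""

    subject_id: str
    fractions: np.ndarray
    lacuna_volume_cm3: float

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("damage fractions must lie in [0, 1]")

    @property
    def damaged_rois(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fractions) > 0)


@dataclass
class Cohort:
    """Everything one simulated (or loaded) study holds in memory."""

    parcellation: Parcellation
    subjects: list[SubjectRecord]
    timeseries: dict[tuple[str, str], RoiTimeSeries] = field(default_factory=dict)
    motion: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    nuisance: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    lesions: dict[str, LesionProfile] = field(default_factory=dict)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def by_group(self, outcome: str, session: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.outcome == outcome and session in s.sessions]

    # ------------------------------------------------------------------ IO

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.parcellation.to_dataframe().to_csv(out / "parcellation.tsv", sep="\t", index=False)

        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "outcome": s.outcome,
                    "laterality": s.laterality,
                    "sessions": "+".join(s.sessions),
                    "age_years": s.age_years,
                    "sex": s.sex,
                    "onset_age_years": s.onset_age_years,
                    "duration_years": s.duration_years,
                    "lacuna_volume_cm3": "" if s.lacuna_volume_cm3 is None else s.lacuna_volume_cm3,
                }
            )
        pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)

        for sub, name in (("timeseries", None), ("motion", None), ("nuisance", None)):
            (out / sub).mkdir(exist_ok=True)
        for (sid, ses), ts in self.timeseries.items():
            pd.DataFrame(ts.data, columns=list(self.parcellation.names)).to_csv(
                out / "timeseries" / f"{sid}_{ses}.tsv", sep="\t", index=False
            )
        mot_cols = ["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"]
        for (sid, ses), m in self.motion.items():
            pd.DataFrame(m, columns=mot_cols).to_csv(
                out / "motion" / f"{sid}_{ses}.tsv", sep="\t", index=False
            )
        for (sid, ses), nz in self.nuisance.items():
            pd.DataFrame(nz, columns=["csf", "wm"]).to_csv(
                out / "nuisance" / f"{sid}_{ses}.tsv", sep="\t", index=False
            )

        les_rows = []
        for sid, prof in self.lesions.items():
            for roi in prof.damaged_rois:
                les_rows.append(
                    {
                        "subject_id": sid,
                        "roi_id": int(roi),
                        "fraction": float(prof.fractions[roi]),
                        "lacuna_volume_cm3": prof.lacuna_volume_cm3,
                    }
                )
        pd.DataFrame(les_rows, columns=["subject_id", "roi_id", "fraction", "lacuna_volume_cm3"]).to_csv(
            out / "lesions.tsv", sep="\t", index=False
        )


def read_cohort(in_dir: str | Path, tr_seconds: float = 2.0) -> Cohort:
    """Load a cohort directory written by :meth:`Cohort.write`."""
    src = Path(in_dir)
    parc = Parcellation.from_dataframe(pd.read_csv(src / "parcellation.tsv", sep="\t"))
    subs_df = pd.read_csv(src / "subjects.tsv", sep="\t")
    subjects = []
    for _, r in subs_df.iterrows():
        vol = r["lacuna_volume_cm3"]
        subjects.append(
            SubjectRecord(
                subject_id=str(r["subject_id"]),
                outcome=str(r["outcome"]),
                laterality=str(r["laterality"]),
                sessions=tuple(str(r["sessions"]).split("+")),
                age_years=float(r["age_years"]),
                sex=str(r["sex"]),
                onset_age_years=float(r["onset_age_years"]),
                duration_years=float(r["duration_years"]),
                lacuna_volume_cm3=None if pd.isna(vol) else float(vol),
            )
        )
    cohort = Cohort(parcellation=parc, subjects=subjects)

    for ts_file in sorted((src / "timeseries").glob("*.tsv")):
        sid, ses = ts_file.stem.rsplit("_", 1)
        data = pd.read_csv(ts_file, sep="\t").to_numpy(dtype=float)
        cohort.timeseries[(sid, ses)] = RoiTimeSeries(sid, ses, data, tr_seconds)
    for m_file in sorted((src / "motion").glob("*.tsv")):
        sid, ses = m_file.stem.rsplit("_", 1)
        cohort.motion[(sid, ses)] = pd.read_csv(m_file, sep="\t").to_numpy(dtype=float)
    for n_file in sorted((src / "nuisance").glob("*.tsv")):
        sid, ses = n_file.stem.rsplit("_", 1)
        cohort.nuisance[(sid, ses)] = pd.read_csv(n_file, sep="\t").to_numpy(dtype=float)

    les_path = src / "lesions.tsv"
    if les_path.exists():
        les = pd.read_csv(les_path, sep="\t")
        for sid, grp in les.groupby("subject_id"):
            fractions = np.zeros(parc.n_rois)
            fractions[grp["roi_id"].to_numpy(int)] = grp["fraction"].to_numpy(float)
            cohort.lesions[str(sid)] = LesionProfile(
                str(sid), fractions, float(grp["lacuna_volume_cm3"].iloc[0])
            )
    return cohort
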