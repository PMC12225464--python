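"""Enforcement-patrol records: data model, CSV I/O, category handling, covariate scaling.

One record is a single land-based enforcement action: when and where it took
place, who and what it targeted, how much effort went into it (minutes spent,
number of enforcers), and whether a violation was detected (binary outcome).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Factor name -> record attribute / column name (identical here).
FACTORS = ("region", "actor", "species", "violation_type", "year")

REQUIRED_COLUMNS = (
    "year",
    "region",
    "actor",
    "species",
    "violation_type",
    "time_minutes",
    "n_enforcers",
    "outcome",
)

#: Default predictor assignment: effort, actor and space/time drive detection;
#: what is being enforced (species, regulation) drives violation occurrence.
DETECTION_TERMS = ("time", "enforcers", "region", "actor", "year")
VIOLATION_TERMS = ("violation_type", "species")

_TERM_TO_FACTOR = {
    "region": "region",
    "actor": "actor",
    "year": "year",
    "violation_type": "violation_type",
    "species": "species",
}


@dataclass(frozen=True)
class EnforcementRecord:
    """A single enforcement action and its outcome."""

    year: int
    region: str
    actor: str
    species: str
    violation_type: str
    time_minutes: float
    n_enforcers: int
    outcome: int

    def __post_init__(self) -> None:
        if self.time_minutes < 0:
            raise ValueError(f"time_minutes must be >= 0, got {self.time_minutes}")
        if self.n_enforcers < 1:
            raise ValueError(f"n_enforcers must be >= 1, got {self.n_enforcers}")
        if self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0 or 1, got {self.outcome}")


@dataclass
class CategoryScheme:
    """Ordered category levels per factor; the first level is the reference.

    All non-reference coefficients in the model are log-odds ratios against the
    reference level, whose coefficient is fixed at zero.
    """

    region_levels: list[str]
    actor_levels: list[str]
    species_levels: list[str]
    violation_levels: list[str]
    year_levels: list[int]

    _ATTR = {
        "region": "region_levels",
        "actor": "actor_levels",
        "species": "species_levels",
        "violation_type": "violation_levels",
        "year": "year_levels",
    }

    def __post_init__(self) -> None:
        for factor in FACTORS:
            lv = self.levels(factor)
            if len(lv) == 0:
                raise ValueError(f"factor {factor!r} has no levels")
            if len(set(lv)) != len(lv):
                raise ValueError(f"duplicate levels in factor {factor!r}")

    def levels(self, factor: str) -> list:
        try:
            return getattr(self, self._ATTR[factor])
        except KeyError:
            raise ValueError(f"unknown factor {factor!r}") from None

    def reference(self, factor: str):
        return self.levels(factor)[0]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CategoryScheme":
        """Infer levels from data, in order of first appearance."""
        def uniq(col):
            return list(pd.unique(frame[col]))

        return cls(
            region_levels=uniq("region"),
            actor_levels=uniq("actor"),
            species_levels=uniq("species"),
            violation_levels=uniq("violation_type"),
            year_levels=[int(y) for y in pd.unique(frame["year"])],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CategoryScheme":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass(frozen=True)
class ScalingInfo:
    """Training-set min/max used to scale the continuous effort covariates to [0, 1]."""

    time_min: float
    time_max: float
    enforcers_min: float
    enforcers_max: float

    def __post_init__(self) -> None:
        if not self.time_max > self.time_min:
            raise ValueError("degenerate scaling: time_max must exceed time_min")
        if not self.enforcers_max > self.enforcers_min:
            raise ValueError("degenerate scaling: enforcers_max must exceed enforcers_min")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScalingInfo":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# record list <-> DataFrame
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[EnforcementRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=REQUIRED_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[EnforcementRecord]:
    return [
        EnforcementRecord(
            year=int(row.year),
            region=str(row.region),
            actor=str(row.actor),
            species=str(row.species),
            violation_type=str(row.violation_type),
            time_minutes=float(row.time_minutes),
            n_enforcers=int(row.n_enforcers),
            outcome=int(row.outcome),
        )
        for row in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_records(path, scheme: CategoryScheme | None = None):
    """Read a patrol-record CSV.

    Returns ``(records, scheme, drop_report)``. Rows failing validation
    (unparseable values, out-of-range effort, unknown categories under a fixed
    scheme) are dropped and counted in ``drop_report``. A missing required
    column is fatal.
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    n_total = len(raw)
    df = raw.copy()
    for col in ("year", "time_minutes", "n_enforcers", "outcome"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = df[list(REQUIRED_COLUMNS)].notna().all(axis=1)
    ok &= (df["time_minutes"] >= 0) & (df["n_enforcers"] >= 1)
    ok &= df["outcome"].isin([0, 1])

    if scheme is not None:
        for factor in ("region", "actor", "species", "violation_type"):
            ok &= df[factor].isin(scheme.levels(factor))
        ok &= df["year"].isin(scheme.year_levels)

    dropped = int(n_total - ok.sum())
    df = df[ok]
    records = frame_to_records(df)
    if scheme is None and records:
        scheme = CategoryScheme.from_frame(records_to_frame(records))
    report = {"total_rows": n_total, "invalid_rows": dropped, "kept_rows": len(records)}
    if dropped:
        warnings.warn(f"dropped {dropped} invalid row(s) while reading {path}")
    return records, scheme, report


def write_records(records: Sequence[EnforcementRecord], path) -> None:
    # %.17g keeps the read/write round trip bit-exact for float fields
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# category collapsing
# ---------------------------------------------------------------------------

def collapse_categories(
    records: Sequence[EnforcementRecord],
    scheme: CategoryScheme,
    factor: str,
    mapping: Mapping,
    allow_new: bool = False,
):
    """Relabel minority levels of ``factor`` according to ``mapping`` (source -> target).

    Record count is conserved; the returned scheme has the source levels removed.
    A mapping target absent from the scheme must be declared via ``allow_new``.
    """
    levels = scheme.levels(factor)
    for src in mapping:
        if src not in levels:
            raise ValueError(f"mapping source {src!r} not a level of {factor!r}")
    for tgt in mapping.values():
        if tgt not in levels and tgt not in mapping and not allow_new:
            raise ValueError(
                f"mapping target {tgt!r} absent from factor {factor!r}; pass allow_new=True"
            )

    new_records = []
    for r in records:
        val = getattr(r, factor)
        if val in mapping:
            r = dataclasses.replace(r, **{factor: mapping[val]})
        new_records.append(r)

    new_levels = [lv for lv in levels if lv not in mapping]
    for tgt in mapping.values():
        if tgt not in new_levels:
            new_levels.append(tgt)
    new_scheme = dataclasses.replace(
        scheme, **{CategoryScheme._ATTR[factor]: new_levels}
    )
    return new_records, new_scheme


# ---------------------------------------------------------------------------
# continuous scaling
# ---------------------------------------------------------------------------

def scale_continuous(frame: pd.DataFrame, info: ScalingInfo | None = None):
    """Min-max scale time and group size to [0, 1].

    With ``info`` given (held-out data), the stored training min/max are
    reused and out-of-range values are clipped with a warning.
    Returns ``(scaled, info)`` with ``scaled`` a DataFrame of columns
    ``time`` and ``enforcers``.
    """
    t = np.asarray(frame["time_minutes"], dtype=float)
    n = np.asarray(frame["n_enforcers"], dtype=float)
    if info is None:
        for name, x in (("time_minutes", t), ("n_enforcers", n)):
            if np.ptp(x) == 0:
                raise ValueError(f"constant column {name!r}: cannot scale to [0, 1]")
        info = ScalingInfo(
            time_min=float(t.min()),
            time_max=float(t.max()),
            enforcers_min=float(n.min()),
            enforcers_max=float(n.max()),
        )
    ts = (t - info.time_min) / (info.time_max - info.time_min)
    ns = (n - info.enforcers_min) / (info.enforcers_max - info.enforcers_min)
    if ((ts < 0) | (ts > 1) | (ns < 0) | (ns > 1)).any():
        warnings.warn("values outside the training range were clipped to [0, 1]")
        ts = np.clip(ts, 0.0, 1.0)
        ns = np.clip(ns, 0.0, 1.0)
    scaled = pd.DataFrame({"time": ts, "enforcers": ns}, index=frame.index)
    return scaled, info


# ---------------------------------------------------------------------------
# collinearity screen
# ---------------------------------------------------------------------------

def collinearity_screen(design: pd.DataFrame, threshold: float = 0.7):
    """Flag predictor pairs with |Pearson r| above ``threshold``.

    Zero-variance columns are excluded with a warning. Returns a list of
    ``(col_a, col_b, r)`` tuples in column order; the caller decides which
    member of a flagged pair to drop.
    """
    cols = list(design.columns)
    X = design.to_numpy(dtype=float)
    variances = X.var(axis=0)
    keep = variances > 0
    if not keep.all():
        dead = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"zero-variance column(s) excluded from screen: {dead}")
        cols = [c for c, k in zip(cols, keep) if k]
        X = X[:, keep]
    if len(cols) < 2:
        return []
    r = np.corrcoef(X, rowvar=False)
    flagged = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(r[i, j]) > threshold:
                flagged.append((cols[i], cols[j], float(r[i, j])))
    return flagged


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Treatment-coded design matrices for the two logit submodels.

    Columns exclude the intercepts (handled as ``mu_p`` / ``mu_v``) and the
    reference level of every factor (coefficient fixed at zero).
    """

    X_det: np.ndarray
    det_names: list[str]
    X_viol: np.ndarray
    viol_names: list[str]
    y: np.ndarray
    scaling: ScalingInfo
    detection_terms: tuple = DETECTION_TERMS
    violation_terms: tuple = VIOLATION_TERMS

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def param_names(self) -> list[str]:
        return ["mu_p"] + self.det_names + ["mu_v"] + self.viol_names

    def drop_columns(self, names: Iterable[str]) -> "Design":
        drop = set(names)
        det_keep = [i for i, nm in enumerate(self.det_names) if nm not in drop]
        viol_keep = [i for i, nm in enumerate(self.viol_names) if nm not in drop]
        return dataclasses.replace(
            self,
            X_det=self.X_det[:, det_keep],
            det_names=[self.det_names[i] for i in det_keep],
            X_viol=self.X_viol[:, viol_keep],
            viol_names=[self.viol_names[i] for i in viol_keep],
        )


def _factor_columns(frame: pd.DataFrame, scheme: CategoryScheme, factor: str):
    levels = scheme.levels(factor)
    col = frame[factor]
    if factor == "year":
        col = col.astype(int)
    unknown = set(col.unique()) - set(levels)
    if unknown:
        raise ValueError(f"unknown level(s) {sorted(map(str, unknown))!r} for factor {factor!r}")
    names, cols = [], []
    for lv in levels[1:]:  # reference level carries no column
        names.append(f"{factor}[{lv}]")
        cols.append((col == lv).to_numpy(dtype=float))
    return names, cols


def build_design(
    frame: pd.DataFrame,
    scheme: CategoryScheme,
    scaling: ScalingInfo | None = None,
    detection_terms: Sequence[str] = DETECTION_TERMS,
    violation_terms: Sequence[str] = VIOLATION_TERMS,
) -> Design:
    """Build the detection/violation design matrices from a record frame."""
    scaled, scaling = scale_continuous(frame, scaling)

    def block(terms):
        names, cols = [], []
        for term in terms:
            if term in ("time", "enforcers"):
                names.append(term)
                cols.append(scaled[term].to_numpy())
            elif term in _TERM_TO_FACTOR:
                nm, cl = _factor_columns(frame, scheme, _TERM_TO_FACTOR[term])
                names.extend(nm)
                cols.extend(cl)
            else:
                raise ValueError(f"unknown model term {term!r}")
        X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
        return X, names

    X_det, det_names = block(detection_terms)
    X_viol, viol_names = block(violation_terms)
    y = frame["outcome"].to_numpy(dtype=int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome column must be binary")
    return Design(
        X_det=X_det,
        det_names=det_names,
        X_viol=X_viol,
        viol_names=viol_names,
        y=y,
        scaling=scaling,
        detection_terms=tuple(detection_terms),
        violation_terms=tuple(violation_terms),
    )
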