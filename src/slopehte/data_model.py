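"""Trial data containers, delimited-text I/O and covariate transforms.

A trial is held as three aligned tables: long-format eGFR measurements
(``subject_id, yrs, egfr``), one-row-per-subject follow-up
(``subject_id, time, event``) and a baseline covariate table
(``subject_id, <covariates...>, trt``).  Times are in years throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSpec",
    "TrialDataset",
    "SchemaError",
    "ConsistencyError",
    "apply_log1p",
    "read_trial",
    "write_trial",
    "split_dataset",
]


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class ConsistencyError(ValueError):
    """The three tables disagree (ids, times, missing baseline...)."""


@dataclass
class CovariateSpec:
    """Covariate layout and transforms.

    ``names`` are the raw covariate columns (order defines the design).
    ``log1p`` lists the continuous columns that receive the log(1+x)
    transform to tame heavy tails; when ``standardize`` is true these same
    columns are centred and scaled after transforming.  ``categorical``
    maps a column to its ordered levels; it is one-hot encoded with the
    first level as reference.  ``roles`` restricts which (encoded) columns
    enter each design: keys ``alpha``, ``beta``, ``gamma``, ``zeta`` (the
    within-leaf / global linear regressions) and ``split`` (tree split
    candidates).  ``None`` means all columns.
    """

    names: list[str]
    log1p: list[str] = field(default_factory=list)
    categorical: dict[str, list] = field(default_factory=dict)
    roles: dict[str, list[str]] | None = None
    standardize: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.log1p) - set(self.names)
        if unknown:
            raise SchemaError(f"log1p columns not in names: {sorted(unknown)}")
        if self.roles:
            encoded = set(self.encoded_names())
            for role, cols in self.roles.items():
                missing = set(cols) - encoded
                if missing:
                    raise SchemaError(f"role {role!r} references unknown columns {sorted(missing)}")

    def encoded_names(self) -> list[str]:
        """Column names after one-hot expansion of categoricals."""
        out: list[str] = []
        for name in self.names:
            if name in self.categorical:
                out.extend(f"{name}={lev}" for lev in self.categorical[name][1:])
            else:
                out.append(name)
        return out

    def role_columns(self, role: str) -> list[str]:
        if self.roles and role in self.roles:
            return list(self.roles[role])
        return self.encoded_names()


@dataclass
class TrialDataset:
    """Aligned longitudinal / survival / covariate data for ``n`` subjects.

    ``cov`` holds the transformed one-hot design columns plus ``trt``;
    ``transform`` records the per-column (shift-applied, mean, sd) so that
    cutpoints can be reported on the original scale.  ``truth`` optionally
    carries the simulator's per-subject true treatment effect.
    """

    long: pd.DataFrame
    surv: pd.DataFrame
    cov: pd.DataFrame
    spec: CovariateSpec
    dropped: int = 0
    transform: dict = field(default_factory=dict)
    truth: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.cov)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.cov["subject_id"].to_numpy()

    def subset(self, ids: np.ndarray) -> "TrialDataset":
        keep = set(ids)
        sub = replace(
            self,
            long=self.long[self.long["subject_id"].isin(keep)].reset_index(drop=True),
            surv=self.surv[self.surv["subject_id"].isin(keep)].reset_index(drop=True),
            cov=self.cov[self.cov["subject_id"].isin(keep)].reset_index(drop=True),
            truth=None
            if self.truth is None
            else self.truth[self.truth["subject_id"].isin(keep)].reset_index(drop=True),
        )
        return sub

    def validate(self) -> None:
        ids = self.cov["subject_id"]
        if ids.duplicated().any():
            raise ConsistencyError("duplicate subject ids in covariate table")
        id_set = set(ids)
        for name, tab in (("longitudinal", self.long), ("survival", self.surv)):
            if set(tab["subject_id"]) != id_set:
                raise ConsistencyError(f"{name} table subject ids do not match covariate table")
        if (self.long["yrs"] < 0).any():
            raise ConsistencyError("negative visit times")
        if not np.isfinite(self.long["egfr"]).all():
            raise ConsistencyError("non-finite eGFR values")
        if (self.surv["time"] <= 0).any():
            raise ConsistencyError("non-positive event/censoring times")
        if not self.surv["event"].isin([0, 1]).all():
            raise SchemaError("event indicator must be 0/1")
        if not self.cov["trt"].isin([0, 1]).all():
            raise SchemaError("treatment indicator must be 0/1")
        has_baseline = self.long.groupby("subject_id")["yrs"].min() == 0
        if not has_baseline.all():
            bad = has_baseline.index[~has_baseline][:5].tolist()
            raise ConsistencyError(f"subjects without a baseline (yrs=0) record: {bad}")
        tmax = self.long.groupby("subject_id")["yrs"].max()
        tend = self.surv.set_index("subject_id")["time"]
        late = tmax > tend.reindex(tmax.index) + 1e-12
        if late.any():
            bad = tmax.index[late][:5].tolist()
            raise ConsistencyError(f"longitudinal records after the event/censoring time: {bad}")


def apply_log1p(x):
    """Natural log of (1+x); domain x > -1."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= -1):
        raise ValueError("log(1+x) requires x > -1")
    out = np.log1p(arr)
    return float(out) if np.isscalar(x) else out


def _read_table(path, columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")
    return df


def read_trial(longitudinal_path, survival_path, covariate_path, spec: CovariateSpec) -> TrialDataset:
    """Read and validate the three trial tables, applying covariate transforms.

    Subjects with any missing covariate are dropped from all three tables and
    counted in ``dataset.dropped``.  Continuous columns in ``spec.log1p`` get
    the log(1+x) transform, then (optionally) standardization; categoricals
    are one-hot encoded with the first listed level as reference.
    """
    long = _read_table(longitudinal_path, ["subject_id", "yrs", "egfr"])
    surv = _read_table(survival_path, ["subject_id", "time", "event"])
    cov = _read_table(covariate_path, ["subject_id", *spec.names, "trt"])

    complete = cov[spec.names].notna().all(axis=1) & cov["trt"].notna()
    dropped = int((~complete).sum())
    keep_ids = set(cov.loc[complete, "subject_id"])
    cov = cov[complete].reset_index(drop=True)
    long = long[long["subject_id"].isin(keep_ids)].reset_index(drop=True)
    surv = surv[surv["subject_id"].isin(keep_ids)].reset_index(drop=True)

    out = pd.DataFrame({"subject_id": cov["subject_id"]})
    transform: dict = {}
    for name in spec.names:
        if name in spec.categorical:
            levels = spec.categorical[name]
            seen = set(cov[name].unique()) - set(levels)
            if seen:
                raise SchemaError(f"{name}: unexpected levels {sorted(map(str, seen))}")
            for lev in levels[1:]:
                out[f"{name}={lev}"] = (cov[name] == lev).astype(float)
            continue
        col = cov[name].astype(float).to_numpy()
        info = {"log1p": name in spec.log1p, "mean": 0.0, "sd": 1.0}
        if info["log1p"]:
            col = apply_log1p(col)
            if spec.standardize:
                info["mean"], info["sd"] = float(col.mean()), float(col.std(ddof=0)) or 1.0
                col = (col - info["mean"]) / info["sd"]
        out[name] = col
        transform[name] = info
    out["trt"] = cov["trt"].astype(int)

    long = long.sort_values(["subject_id", "yrs"], kind="stable").reset_index(drop=True)
    ds = TrialDataset(long=long, surv=surv, cov=out, spec=spec, dropped=dropped, transform=transform)
    ds.validate()
    return ds


def write_trial(data: TrialDataset, longitudinal_path, survival_path, covariate_path) -> None:
    """Write the three tables back to CSV (transformed covariate scale)."""
    data.long.to_csv(longitudinal_path, index=False)
    data.surv.to_csv(survival_path, index=False)
    data.cov.to_csv(covariate_path, index=False)


def inverse_transform_cut(data: TrialDataset, column: str, value: float) -> float:
    """Map a cutpoint on the modelling scale back to the raw covariate scale."""
    info = data.transform.get(column)
    if not info:
        return value
    v = value * info["sd"] + info["mean"]
    return float(np.expm1(v)) if info["log1p"] else float(v)


def split_dataset(data: TrialDataset, frac_discovery: float, seed: int):
    """Subject-level 60/40-style split, stratified by treatment arm.

    Returns ``(discovery, validation)``; the discovery size is
    ``floor(n * frac_discovery)`` exactly, allocated across arms by largest
    remainder so neither arm is degenerate.
    """
    if not 0.0 < frac_discovery < 1.0:
        raise ValueError("frac_discovery must be in (0, 1)")
    if data.n < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    target = int(np.floor(data.n * frac_discovery))
    ids = data.cov["subject_id"].to_numpy()
    trt = data.cov["trt"].to_numpy()
    picks: list[np.ndarray] = []
    quotas = []
    for arm in (0, 1):
        arm_ids = ids[trt == arm]
        quotas.append(len(arm_ids) * frac_discovery)
        picks.append(arm_ids)
    base = [int(np.floor(q)) for q in quotas]
    # largest-remainder allocation to hit the total exactly
    rem = sorted(range(2), key=lambda a: quotas[a] - base[a], reverse=True)
    short = target - sum(base)
    for a in rem[: max(short, 0)]:
        base[a] += 1
    disc_ids: list = []
    for arm, take in zip((0, 1), base):
        arm_ids = picks[arm]
        perm = rng.permutation(len(arm_ids))
        disc_ids.extend(arm_ids[perm[:take]])
    disc_set = set(disc_ids)
    val_ids = np.array([i for i in ids if i not in disc_set])
    return data.subset(np.array(list(disc_ids))), data.subset(val_ids)
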