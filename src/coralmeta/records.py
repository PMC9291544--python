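"""Domain types and file I/O for experiment records, scenarios and config.

The on-disk experiment format is a tidy UTF-8 CSV in "long contrast" form:
one row per control/treatment contrast.  Rows belonging to a full-factorial
experiment share a ``quad_id`` and carry arm types ``warming``, ``co2`` and
``both``; groups covering all three treatment arms are assembled into
:class:`FactorialQuad` objects (the control arm is shared), while incomplete
groups fall back to plain two-arm records.

Column headers are configurable through a mapping (canonical name -> file
header) because deposited datasets rarely share a header convention.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from coralmeta.errors import RecordValidationError, SchemaError

logger = logging.getLogger(__name__)

ATTRIBUTES = (
    "symbiont_density",
    "chla",
    "photochemical_efficiency",
    "photosynthesis",
    "respiration",
    "calcification",
    "growth",
    "survival",
)

ARM_TYPES = ("warming", "co2", "both")

RCPS = ("RCP2.6", "RCP4.5", "RCP6.0", "RCP8.5")
PERIODS = (
    "near_term_2021_2040",
    "mid_century_2041_2060",
    "late_century_2081_2100",
    "end_of_century_2091_2100",
)

#: canonical experiment CSV columns, in write order
EXPERIMENT_COLUMNS = (
    "study_id", "genus", "species", "attribute", "arm_type",
    "control_mean", "control_sd", "control_n",
    "treatment_mean", "treatment_sd", "treatment_n",
    "t_control_C", "t_treatment_C",
    "pco2_control_uatm", "pco2_treatment_uatm",
    "duration_days", "quad_id", "co_stressor",
)

_REQUIRED_COLUMNS = (
    "study_id", "genus", "attribute", "arm_type",
    "control_mean", "control_sd", "control_n",
    "treatment_mean", "treatment_sd", "treatment_n",
)


@dataclass(frozen=True)
class ExperimentRecord:
    """One control/treatment contrast for a single coral attribute.

    ``arm_type`` states which driver differs between the arms: ``warming``
    (temperature only), ``co2`` (pCO2 only) or ``both``.  Temperatures are
    degrees Celsius; pCO2 in µatm.
    """

    study_id: str
    genus: str
    attribute: str
    arm_type: str
    control_mean: float
    control_sd: float
    control_n: int
    treatment_mean: float
    treatment_sd: float
    treatment_n: int
    t_control_C: float = math.nan
    t_treatment_C: float = math.nan
    pco2_control_uatm: float = math.nan
    pco2_treatment_uatm: float = math.nan
    species: str = ""
    duration_days: float = math.nan
    quad_id: str = ""
    #: True when the non-varying driver is held at an elevated level in both
    #: arms (e.g. a warming contrast run under elevated pCO2)
    co_stressor: bool = False

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.attribute not in ATTRIBUTES:
            problems.append(f"unknown attribute {self.attribute!r}")
        if self.arm_type not in ARM_TYPES:
            problems.append(f"unknown arm_type {self.arm_type!r}")
        if not (self.control_n >= 1 and self.treatment_n >= 1):
            problems.append("sample sizes must be >= 1")
        if self.control_sd < 0 or self.treatment_sd < 0:
            problems.append("SDs must be >= 0")
        if not (self.control_mean > 0 and self.treatment_mean > 0):
            problems.append("means must be strictly positive for log ratios")
        if self.arm_type in ("warming", "both"):
            if not self.t_treatment_C > self.t_control_C:
                problems.append("warming contrast requires t_treatment_C > t_control_C")
        if self.arm_type in ("co2", "both"):
            if not self.pco2_treatment_uatm > self.pco2_control_uatm:
                problems.append(
                    "co2 contrast requires pco2_treatment_uatm > pco2_control_uatm"
                )
        return problems

    @property
    def delta_T_C(self) -> float:
        return self.t_treatment_C - self.t_control_C

    @property
    def delta_pco2_uatm(self) -> float:
        return self.pco2_treatment_uatm - self.pco2_control_uatm


@dataclass(frozen=True)
class Arm:
    """Summary statistics of one treatment arm."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class FactorialQuad:
    """A full-factorial warming x CO2 experiment: four arms sharing a control.

    ``t_treatment_C`` / ``pco2_treatment_uatm`` are the elevated levels used
    in the warming-containing / CO2-containing arms.
    """

    study_id: str
    genus: str
    attribute: str
    control: Arm
    warming: Arm
    co2: Arm
    both: Arm
    t_control_C: float = math.nan
    t_treatment_C: float = math.nan
    pco2_control_uatm: float = math.nan
    pco2_treatment_uatm: float = math.nan
    species: str = ""
    quad_id: str = ""

    def arms(self) -> dict[str, Arm]:
        return {
            "control": self.control,
            "warming": self.warming,
            "co2": self.co2,
            "both": self.both,
        }

    def validate(self) -> list[str]:
        problems = []
        if self.attribute not in ATTRIBUTES:
            problems.append(f"unknown attribute {self.attribute!r}")
        for name, arm in self.arms().items():
            if arm.n < 2:
                problems.append(f"arm {name!r} needs n >= 2 for a pooled SD")
            if arm.sd < 0:
                problems.append(f"arm {name!r} has negative SD")
            if not arm.mean > 0:
                problems.append(f"arm {name!r} mean must be positive")
        return problems


@dataclass(frozen=True)
class ScenarioSpec:
    """One emissions-scenario increment: MHW warming and/or pCO2 rise above present."""

    rcp: str
    period: str
    delta_T_C: float = 0.0
    delta_pco2_uatm: float = 0.0

    def validate(self) -> list[str]:
        problems = []
        if self.rcp not in RCPS:
            problems.append(f"unknown rcp {self.rcp!r}")
        if self.period not in PERIODS:
            problems.append(f"unknown period {self.period!r}")
        if self.delta_T_C < 0 or self.delta_pco2_uatm < 0:
            problems.append("scenario deltas must be >= 0")
        if self.delta_T_C == 0 and self.delta_pco2_uatm == 0:
            problems.append("at least one scenario delta must be set")
        return problems


@dataclass
class PipelineConfig:
    """Run-wide configuration; every stochastic stage derives from ``seed``."""

    boltzmann_k: float = 8.617e-5  # eV / K
    baseline_temperature_C: float = 27.0
    sensitivity_step_T_C: float = 0.01
    sensitivity_step_pco2_uatm: float = 1.0
    sensitivity_cap_T_C: float = 13.0
    sensitivity_cap_pco2_uatm: float = 800.0
    significance_alpha: float = 0.05
    mhw_percentile: float = 90.0
    mhw_min_duration: int = 1
    variance_floor: float = 1e-10
    strict: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.mhw_percentile < 100:
            raise ValueError("mhw_percentile must lie strictly between 0 and 100")
        if self.sensitivity_step_T_C <= 0 or self.sensitivity_step_pco2_uatm <= 0:
            raise ValueError("sensitivity steps must be > 0")
        if not 0 < self.significance_alpha < 1:
            raise ValueError("significance_alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def _rename_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        inverse = {v: k for k, v in column_map.items()}
        df = df.rename(columns=inverse)
    return df


def _row_to_record(row: pd.Series) -> ExperimentRecord:
    def _s(key, default=""):
        val = row.get(key)
        return default if val is None or (isinstance(val, float) and math.isnan(val)) else str(val)

    def _f(key):
        val = row.get(key)
        return math.nan if val is None else float(val)

    return ExperimentRecord(
        study_id=_s("study_id"),
        genus=_s("genus"),
        species=_s("species"),
        attribute=_s("attribute"),
        arm_type=_s("arm_type"),
        control_mean=_f("control_mean"),
        control_sd=_f("control_sd"),
        control_n=int(row["control_n"]),
        treatment_mean=_f("treatment_mean"),
        treatment_sd=_f("treatment_sd"),
        treatment_n=int(row["treatment_n"]),
        t_control_C=_f("t_control_C"),
        t_treatment_C=_f("t_treatment_C"),
        pco2_control_uatm=_f("pco2_control_uatm"),
        pco2_treatment_uatm=_f("pco2_treatment_uatm"),
        duration_days=_f("duration_days"),
        quad_id=_s("quad_id"),
        co_stressor=str(row.get("co_stressor", "")).strip().lower()
        in ("true", "1", "yes"),
    )


def _assemble_quad(group: list[ExperimentRecord]) -> FactorialQuad | None:
    """Build a FactorialQuad from records sharing a quad_id, or None if the
    group does not cover the warming, co2 and both arms."""
    by_type = {rec.arm_type: rec for rec in group}
    if set(by_type) != {"warming", "co2", "both"} or len(group) != 3:
        return None
    w, c, b = by_type["warming"], by_type["co2"], by_type["both"]
    quad = FactorialQuad(
        study_id=w.study_id,
        genus=w.genus,
        species=w.species,
        attribute=w.attribute,
        control=Arm(w.control_mean, w.control_sd, w.control_n),
        warming=Arm(w.treatment_mean, w.treatment_sd, w.treatment_n),
        co2=Arm(c.treatment_mean, c.treatment_sd, c.treatment_n),
        both=Arm(b.treatment_mean, b.treatment_sd, b.treatment_n),
        t_control_C=w.t_control_C,
        t_treatment_C=w.t_treatment_C,
        pco2_control_uatm=c.pco2_control_uatm,
        pco2_treatment_uatm=c.pco2_treatment_uatm,
        quad_id=w.quad_id,
    )
    return quad if not quad.validate() else None


def read_experiments(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    strict: bool = False,
) -> tuple[list[ExperimentRecord], list[FactorialQuad], pd.DataFrame]:
    """Read an experiment CSV into validated records and factorial quads.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    column_map : mapping, optional
        canonical column name -> header used in the file.
    strict : bool
        If True, any invalid row raises :class:`RecordValidationError`;
        otherwise invalid rows are logged, dropped, and listed in the report.

    Returns
    -------
    records : list of ExperimentRecord
        Two-arm contrasts (rows not absorbed into a complete quad).
    quads : list of FactorialQuad
        Complete full-factorial groups.
    report : DataFrame
        One row per excluded input row with its 1-based row number and reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    df = _rename_columns(df, column_map)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    rows: list[tuple[int, ExperimentRecord]] = []
    bad: list[tuple[int, str]] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            rec = _row_to_record(row)
        except (ValueError, TypeError, KeyError) as exc:
            bad.append((i, f"unparseable row: {exc}"))
            continue
        problems = rec.validate()
        if problems:
            bad.append((i, "; ".join(problems)))
        else:
            rows.append((i, rec))

    if bad and strict:
        raise RecordValidationError(
            "invalid rows: " + "; ".join(f"row {i}: {msg}" for i, msg in bad),
            rows=[i for i, _ in bad],
        )
    for i, msg in bad:
        logger.warning("dropping row %d: %s", i, msg)

    # group complete factorial quads; leave the rest as two-arm records
    records: list[ExperimentRecord] = []
    quads: list[FactorialQuad] = []
    groups: dict[str, list[ExperimentRecord]] = {}
    for _, rec in rows:
        if rec.quad_id:
            groups.setdefault(rec.quad_id, []).append(rec)
        else:
            records.append(rec)
    for qid, group in groups.items():
        quad = _assemble_quad(group)
        if quad is not None:
            quads.append(quad)
        else:
            logger.info("quad %s incomplete; keeping %d two-arm records", qid, len(group))
            records.extend(group)

    report = pd.DataFrame(bad, columns=["row", "reason"])
    return records, quads, report


def records_to_frame(
    records: Iterable[ExperimentRecord],
    quads: Iterable[FactorialQuad] = (),
) -> pd.DataFrame:
    """Flatten records (and quads back into long contrast rows) to a DataFrame."""
    out = [dataclasses.asdict(rec) for rec in records]
    for q in quads:
        shared = dict(study_id=q.study_id, genus=q.genus, species=q.species,
                      attribute=q.attribute, quad_id=q.quad_id,
                      duration_days=math.nan)
        ctl = dict(control_mean=q.control.mean, control_sd=q.control.sd,
                   control_n=q.control.n)
        out.append(dict(shared, arm_type="warming", **ctl,
                        treatment_mean=q.warming.mean, treatment_sd=q.warming.sd,
                        treatment_n=q.warming.n,
                        t_control_C=q.t_control_C, t_treatment_C=q.t_treatment_C,
                        pco2_control_uatm=math.nan, pco2_treatment_uatm=math.nan))
        out.append(dict(shared, arm_type="co2", **ctl,
                        treatment_mean=q.co2.mean, treatment_sd=q.co2.sd,
                        treatment_n=q.co2.n,
                        t_control_C=math.nan, t_treatment_C=math.nan,
                        pco2_control_uatm=q.pco2_control_uatm,
                        pco2_treatment_uatm=q.pco2_treatment_uatm))
        out.append(dict(shared, arm_type="both", **ctl,
                        treatment_mean=q.both.mean, treatment_sd=q.both.sd,
                        treatment_n=q.both.n,
                        t_control_C=q.t_control_C, t_treatment_C=q.t_treatment_C,
                        pco2_control_uatm=q.pco2_control_uatm,
                        pco2_treatment_uatm=q.pco2_treatment_uatm))
    return pd.DataFrame(out, columns=list(EXPERIMENT_COLUMNS))


def write_experiments(
    path: str | Path,
    records: Iterable[ExperimentRecord],
    quads: Iterable[FactorialQuad] = (),
) -> None:
    """Write records and quads to the canonical long-contrast CSV."""
    records_to_frame(records, quads).to_csv(path, index=False)


def read_scenarios(path: str | Path) -> list[ScenarioSpec]:
    """Read a scenario table CSV (rcp, period, delta_T_C, delta_pco2_uatm)."""
    df = pd.read_csv(path)
    required = ["rcp", "period"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"scenario table missing columns: {missing}")
    out = []
    bad_rows = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        spec = ScenarioSpec(
            rcp=str(row.rcp),
            period=str(row.period),
            delta_T_C=float(getattr(row, "delta_T_C", 0.0) or 0.0),
            delta_pco2_uatm=float(getattr(row, "delta_pco2_uatm", 0.0) or 0.0),
        )
        problems = spec.validate()
        if problems:
            bad_rows.append((i, "; ".join(problems)))
        else:
            out.append(spec)
    if bad_rows:
        raise RecordValidationError(
            "invalid scenario rows: " + "; ".join(f"row {i}: {m}" for i, m in bad_rows),
            rows=[i for i, _ in bad_rows],
        )
    return out
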