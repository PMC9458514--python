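"""Model parameters: typed containers, YAML (de)serialisation and validation.

Every model input is a :class:`Param` — a base-case value plus the (low, high)
range used by the deterministic and probabilistic sensitivity analyses.  The
packaged YAML files under ``pdac_cea/data`` hold the published base-case
values; :func:`load_parameters` reads and validates them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "Param",
    "GeneralParams",
    "StrategyParams",
    "ModelSettings",
    "ValidationError",
    "load_parameters",
    "load_general",
    "load_strategy",
    "load_settings",
    "save_yaml",
    "data_path",
    "ARM_FOLFIRINOX",
    "ARM_GNP",
    "ARM_NATURAL_HISTORY",
    "ARMS",
]

ARM_FOLFIRINOX = "FOLFIRINOX"
ARM_GNP = "G-nP"
ARM_NATURAL_HISTORY = "Natural history"
ARMS = (ARM_NATURAL_HISTORY, ARM_GNP, ARM_FOLFIRINOX)

_DATA_DIR = Path(__file__).parent / "data"


def data_path(name: str) -> Path:
    """Path of a packaged data file."""
    return _DATA_DIR / name


class ValidationError(ValueError):
    """A parameter violated its declared bounds; ``field`` names the culprit."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class Param:
    """A model input: base-case value with a sensitivity range."""

    base: float
    low: float
    high: float

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                "range", f"low <= base <= high violated: ({self.low}, {self.base}, {self.high})"
            )

    def replace(self, base: float) -> "Param":
        p = object.__new__(Param)  # bypass range check: DSA may probe the bound itself
        object.__setattr__(p, "base", base)
        object.__setattr__(p, "low", min(self.low, base))
        object.__setattr__(p, "high", max(self.high, base))
        return p


# bound kinds for validation
_PROB = "probability"
_UTILITY = "utility"
_COST = "cost"
_MONTHS = "months"
_DISUTILITY = "disutility"
_AGE = "age"


def _check(kind: str, name: str, value: float) -> None:
    if kind in (_PROB, _UTILITY) and not (0.0 <= value <= 1.0):
        raise ValidationError(name, f"{kind} must lie in [0, 1], got {value}")
    if kind == _COST and value < 0:
        raise ValidationError(name, f"cost must be >= 0, got {value}")
    if kind == _MONTHS and value <= 0:
        raise ValidationError(name, f"months must be > 0, got {value}")
    if kind == _DISUTILITY and value > 0:
        raise ValidationError(name, f"disutility must be <= 0, got {value}")
    if kind == _AGE and value <= 0:
        raise ValidationError(name, f"age must be > 0, got {value}")


@dataclass(frozen=True)
class GeneralParams:
    """Strategy-independent inputs: baseline rates, utilities and costs."""

    start_age: Param = field(metadata={"kind": _AGE})
    neoadjuvant_30day_mortality: Param = field(metadata={"kind": _PROB})
    surgical_30day_mortality: Param = field(metadata={"kind": _PROB})
    postsurgical_fistula_rate: Param = field(metadata={"kind": _PROB})
    utility_progression_free: Param = field(metadata={"kind": _UTILITY})
    utility_progressive: Param = field(metadata={"kind": _UTILITY})
    utility_palliative: Param = field(metadata={"kind": _UTILITY})
    utility_surgery_recovery: Param = field(metadata={"kind": _UTILITY})
    cost_resection: Param = field(metadata={"kind": _COST})
    cost_palliative_total: Param = field(metadata={"kind": _COST})
    cost_capecitabine_rt_month: Param = field(metadata={"kind": _COST})
    cost_chemoradiation_hosp: Param = field(metadata={"kind": _COST})
    cost_eus: Param = field(metadata={"kind": _COST})
    cost_pdac_month_inpatient: Param = field(metadata={"kind": _COST})

    def __post_init__(self):
        _validate_params(self)


#: StrategyParams fields that only exist for treated arms.
TREATMENT_FIELDS = (
    "dropout_rate",
    "toxicity_rate",
    "hospitalization_for_toxicity",
    "surgical_complication_rate",
    "fistula_rate",
    "r0_rate",
    "recurrence_rate",
    "lymph_node_positivity",
    "median_surv_recurrence_r0",
    "median_surv_recurrence_r1",
    "median_surv_recurrence_n0",
    "median_surv_recurrence_n1",
    "median_surv_second_line",
    "cost_chemo_cycle",
    "cost_toxicity_cycle",
    "cost_second_line_month",
    "cost_toxicity_second_line_month",
    "cost_admin_month",
    "disutility_chemo",
    "disutility_toxicity",
)


@dataclass(frozen=True)
class StrategyParams:
    """Arm-specific inputs.  The natural-history arm carries no treatment fields."""

    name: str
    treated: bool = True
    n_cycles: int = 6
    cycle_days: str = ""
    dropout_rate: Param | None = field(default=None, metadata={"kind": _PROB})
    toxicity_rate: Param | None = field(default=None, metadata={"kind": _PROB})
    hospitalization_for_toxicity: Param | None = field(default=None, metadata={"kind": _PROB})
    surgical_complication_rate: Param | None = field(default=None, metadata={"kind": _PROB})
    fistula_rate: Param | None = field(default=None, metadata={"kind": _PROB})
    r0_rate: Param | None = field(default=None, metadata={"kind": _PROB})
    recurrence_rate: Param | None = field(default=None, metadata={"kind": _PROB})
    lymph_node_positivity: Param | None = field(default=None, metadata={"kind": _PROB})
    median_surv_recurrence_r0: Param | None = field(default=None, metadata={"kind": _MONTHS})
    median_surv_recurrence_r1: Param | None = field(default=None, metadata={"kind": _MONTHS})
    median_surv_recurrence_n0: Param | None = field(default=None, metadata={"kind": _MONTHS})
    median_surv_recurrence_n1: Param | None = field(default=None, metadata={"kind": _MONTHS})
    median_surv_second_line: Param | None = field(default=None, metadata={"kind": _MONTHS})
    cost_chemo_cycle: Param | None = field(default=None, metadata={"kind": _COST})
    cost_toxicity_cycle: Param | None = field(default=None, metadata={"kind": _COST})
    cost_second_line_month: Param | None = field(default=None, metadata={"kind": _COST})
    cost_toxicity_second_line_month: Param | None = field(default=None, metadata={"kind": _COST})
    cost_admin_month: Param | None = field(default=None, metadata={"kind": _COST})
    disutility_chemo: Param | None = field(default=None, metadata={"kind": _DISUTILITY})
    disutility_toxicity: Param | None = field(default=None, metadata={"kind": _DISUTILITY})

    def __post_init__(self):
        if self.treated:
            for name in TREATMENT_FIELDS:
                if getattr(self, name) is None:
                    raise ValidationError(name, "missing field for treated arm")
        _validate_params(self)

    def with_value(self, field_name: str, value: float) -> "StrategyParams":
        """Copy with one parameter's base value replaced (sensitivity analyses)."""
        cur = getattr(self, field_name)
        return dataclasses.replace(self, **{field_name: cur.replace(value)})


@dataclass(frozen=True)
class ModelSettings:
    """Run-level settings: horizon, discounting, thresholds and modelling options.

    The ``dropout_split_*`` fractions allocate patients who do not complete
    neoadjuvant therapy to second-line treatment, palliative care, or death.
    ``palliative_median_months`` sets the assumed median survival in the
    palliative state for the treated arms (untreated post-progression survival
    is calibrated instead).
    """

    horizon_cycles: int = 144
    cycle_length_months: float = 1.0
    discount_rate_annual: float = 0.03
    wtp_thresholds: tuple = (50_000.0, 100_000.0, 150_000.0)
    psa_iterations: int = 10_000
    rng_seed: int = 1
    dropout_split_second_line: float = 0.5
    dropout_split_palliative: float = 0.3
    dropout_split_death: float = 0.2
    palliative_median_months: float = 5.1
    surgery_recovery_cycles: int = 1
    chemoradiation_addon: bool = True
    recurrence_second_line: bool = True
    toxicity_hospitalization_inpatient: bool = True

    def __post_init__(self):
        if self.horizon_cycles <= 0:
            raise ValidationError("horizon_cycles", "must be > 0")
        if not (0.0 <= self.discount_rate_annual < 1.0):
            raise ValidationError("discount_rate_annual", "must lie in [0, 1)")
        split = (
            self.dropout_split_second_line
            + self.dropout_split_palliative
            + self.dropout_split_death
        )
        if abs(split - 1.0) > 1e-9:
            raise ValidationError("dropout_split", f"fractions must sum to 1, got {split}")


def _validate_params(obj) -> None:
    for f in fields(obj):
        kind = f.metadata.get("kind")
        value = getattr(obj, f.name)
        if kind is None or value is None:
            continue
        if isinstance(value, Param):
            for attr in ("base", "low", "high"):
                _check(kind, f.name, getattr(value, attr))
        else:
            _check(kind, f.name, value)


# ---------------------------------------------------------------------------
# YAML I/O


def _param_from_yaml(name: str, node) -> Param:
    if isinstance(node, dict):
        try:
            return Param(float(node["base"]), float(node["low"]), float(node["high"]))
        except KeyError as exc:
            raise ValidationError(name, f"missing range key {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(name, str(exc)) from exc
    value = float(node)
    return Param(value, value, value)


def _load_yaml(path: Path | str) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(str(path), "expected a YAML mapping")
    return doc


def _build(cls, doc: dict, path) -> object:
    kwargs = {}
    for f in fields(cls):
        if f.name not in doc:
            if f.default is not dataclasses.MISSING or f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
                continue
            raise ValidationError(f.name, f"missing field in {path}")
        node = doc.pop(f.name)
        if f.metadata.get("kind") is not None:
            kwargs[f.name] = _param_from_yaml(f.name, node) if node is not None else None
        elif f.name == "wtp_thresholds":
            kwargs[f.name] = tuple(float(v) for v in node)
        else:
            kwargs[f.name] = node
    if doc:
        raise ValidationError(next(iter(doc)), f"unknown field in {path}")
    return cls(**kwargs)


def load_general(path: Path | str | None = None) -> GeneralParams:
    path = data_path("general.yaml") if path is None else path
    return _build(GeneralParams, _load_yaml(path), path)


def load_strategy(path: Path | str) -> StrategyParams:
    return _build(StrategyParams, _load_yaml(path), path)


def load_settings(path: Path | str | None = None) -> ModelSettings:
    path = data_path("settings.yaml") if path is None else path
    return _build(ModelSettings, _load_yaml(path), path)


_ARM_FILES = {
    ARM_FOLFIRINOX: "folfirinox.yaml",
    ARM_GNP: "gnp.yaml",
    ARM_NATURAL_HISTORY: "natural_history.yaml",
}


def load_parameters(directory: Path | str | None = None):
    """Load (general, [strategies], settings) from a directory of YAML files.

    ``directory=None`` loads the packaged base-case files transcribed from the
    published tables.  All invariants are validated on load; violations raise
    :class:`ValidationError` naming the offending field.
    """
    directory = _DATA_DIR if directory is None else Path(directory)
    general = load_general(directory / "general.yaml")
    strategies = [load_strategy(directory / _ARM_FILES[arm]) for arm in ARMS]
    settings = load_settings(directory / "settings.yaml")
    return general, strategies, settings


def _to_node(value):
    if isinstance(value, Param):
        return {"base": value.base, "low": value.low, "high": value.high}
    if isinstance(value, tuple):
        return list(value)
    return value


def save_yaml(obj, path: Path | str) -> None:
    """Write a parameter object back to YAML (round-trips with the loaders)."""
    doc = {}
    for f in fields(obj):
        value = getattr(obj, f.name)
        if value is None:
            continue
        doc[f.name] = _to_node(value)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def iter_ranged_params(
    general: GeneralParams, strategies: list[StrategyParams]
) -> Iterator[tuple[str, str, str, Param]]:
    """Yield (owner, field, label, Param) for every input with a non-degenerate range.

    ``owner`` is ``"general"`` or the strategy name; ``label`` is unique.
    """
    for f in fields(general):
        p = getattr(general, f.name)
        if isinstance(p, Param):
            yield "general", f.name, f"general.{f.name}", p
    for strat in strategies:
        if not strat.treated:
            continue
        for name in TREATMENT_FIELDS:
            p = getattr(strat, name)
            if isinstance(p, Param):
                yield strat.name, name, f"{strat.name}.{name}", p
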