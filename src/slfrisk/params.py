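"""Species parameter sets for the cohort degree-day model.

Parameters use the field-standard short codes (``eggLDT``, ``larvaeDD``,
``distro_mean`` ...) so that parameter files round-trip verbatim.  The
shipped defaults describe the spotted lanternfly (*Lycorma delicatula*):
a univoltine insect that overwinters as an egg, with a common lower
developmental threshold of 10 degC and an upper threshold of 35 degC for
every stage.  Stage names follow the four-stage modelling convention:
"larva" is the nymphal period (instars 1-4), "pupa" the pre-oviposition
adult period, and "adult" the first-to-50%-oviposition period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

__all__ = [
    "ThermalThresholds",
    "StressParams",
    "SpeciesParams",
    "read_params_file",
    "write_params_file",
]

#: Life-stage order: overwintered egg, larva (nymphs), pupa
#: (pre-oviposition adult), adult (ovipositing), first-generation egg.
STAGE_ORDER = ("OE", "L", "P", "A", "E")


@dataclass(frozen=True)
class ThermalThresholds:
    """Lower/upper developmental temperature thresholds in degC."""

    ldt: float
    udt: float

    def __post_init__(self) -> None:
        if not self.udt > self.ldt:
            raise ValueError(
                f"upper threshold must exceed lower threshold "
                f"(got ldt={self.ldt}, udt={self.udt})"
            )


@dataclass(frozen=True)
class StressParams:
    """Cold/heat stress thresholds (degC) and exclusion limits (degC-days).

    Stress units accumulate when daily temperatures cross the thresholds;
    annual accumulations beyond ``max1`` mark moderate exclusion (most
    individuals die; long-term establishment inhibited) and beyond
    ``max2`` severe exclusion (all individuals die).
    """

    coldstress_threshold: float = -16.0
    coldstress_units_max1: float = 300.0
    coldstress_units_max2: float = 475.0
    heatstress_threshold: float = 37.0
    heatstress_units_max1: float = 115.0
    heatstress_units_max2: float = 175.0

    def __post_init__(self) -> None:
        for kind in ("coldstress", "heatstress"):
            m1 = getattr(self, f"{kind}_units_max1")
            m2 = getattr(self, f"{kind}_units_max2")
            if not (m2 > m1 > 0):
                raise ValueError(
                    f"{kind} limits must satisfy max2 > max1 > 0 "
                    f"(got max1={m1}, max2={m2})"
                )


@dataclass
class SpeciesParams:
    """Full parameter set for the phenology + suitability model.

    Degree-day quantities are in degC-days above the stage's lower
    threshold.  ``distro_mean``/``distro_var``/``xdist1``/``xdist2``
    describe the (truncated) normal distribution of degree-days required
    to complete overwintered-egg development, discretised into
    ``n_cohorts`` population cohorts.
    """

    # lower developmental thresholds (degC)
    eggLDT: float = 10.0
    larvaeLDT: float = 10.0
    pupaeLDT: float = 10.0
    adultLDT: float = 10.0
    # upper developmental thresholds (degC)
    eggUDT: float = 35.0
    larvaeUDT: float = 35.0
    pupaeUDT: float = 35.0
    adultUDT: float = 35.0
    # stage durations (degC-days)
    eggDD: float = 202.0
    larvaeDD: float = 890.0
    pupDD: float = 630.0
    adultDD: float = 146.0
    # phenological event triggers (degC-days within the stage);
    # egg hatch (OWEventDD) varies per cohort and is set by the cohort
    # requirement, so it carries no fixed value here.
    larvaeEventDD: float = 442.0
    pupaeEventDD: float = 1.0
    adultEventDD: float = 1.0
    eggEventDD: float = 100.0
    # cohort distribution of overwintered-egg development requirements
    distro_mean: float = 190.0
    distro_var: float = 15000.0
    xdist1: float = 135.0
    xdist2: float = 360.0
    distro_shape: str = "normal"
    n_cohorts: int = 7
    # life cycle structure
    stgorder: tuple[str, ...] = STAGE_ORDER
    obligate_diapause: bool = True
    calctype: str = "triangle"
    # climatic stress
    stress: StressParams = field(default_factory=StressParams)

    def __post_init__(self) -> None:
        if not (self.xdist1 < self.distro_mean < self.xdist2):
            raise ValueError(
                "cohort bounds must satisfy xdist1 < distro_mean < xdist2 "
                f"(got {self.xdist1}, {self.distro_mean}, {self.xdist2})"
            )
        for name in ("eggDD", "larvaeDD", "pupDD", "adultDD", "distro_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")
        if tuple(self.stgorder) != STAGE_ORDER:
            raise ValueError(f"stage order must be {STAGE_ORDER}")
        if self.distro_shape != "normal":
            raise ValueError("only a normal cohort distribution is supported")
        if self.calctype != "triangle":
            raise ValueError("only the single-triangle calculation is supported")

    # -- derived views ---------------------------------------------------

    def stage_thresholds(self, stage: str) -> ThermalThresholds:
        """Thermal thresholds for a stage code from ``stgorder``.

        Both egg stages (overwintered "OE" and first-generation "E")
        use the egg thresholds.
        """
        table = {
            "OE": (self.eggLDT, self.eggUDT),
            "L": (self.larvaeLDT, self.larvaeUDT),
            "P": (self.pupaeLDT, self.pupaeUDT),
            "A": (self.adultLDT, self.adultUDT),
            "E": (self.eggLDT, self.eggUDT),
        }
        ldt, udt = table[stage]
        return ThermalThresholds(ldt, udt)

    def stage_duration(self, stage: str) -> float:
        """Degree-days to complete a stage (OE varies per cohort)."""
        table = {
            "L": self.larvaeDD,
            "P": self.pupDD,
            "A": self.adultDD,
            "E": self.eggDD,
        }
        if stage == "OE":
            raise ValueError("overwintered-egg duration is a cohort property")
        return table[stage]

    def to_flat_dict(self) -> dict[str, str]:
        d = asdict(self)
        stress = d.pop("stress")
        d.update(stress)
        d["stgorder"] = ",".join(self.stgorder)
        d["obligate_diapause"] = "1" if self.obligate_diapause else "0"
        return {k: str(v) for k, v in d.items()}


_FLOAT_KEYS = {
    "eggLDT", "larvaeLDT", "pupaeLDT", "adultLDT",
    "eggUDT", "larvaeUDT", "pupaeUDT", "adultUDT",
    "eggDD", "larvaeDD", "pupDD", "adultDD",
    "larvaeEventDD", "pupaeEventDD", "adultEventDD", "eggEventDD",
    "distro_mean", "distro_var", "xdist1", "xdist2",
    "coldstress_threshold", "coldstress_units_max1", "coldstress_units_max2",
    "heatstress_threshold", "heatstress_units_max1", "heatstress_units_max2",
}
_STRESS_KEYS = {
    "coldstress_threshold", "coldstress_units_max1", "coldstress_units_max2",
    "heatstress_threshold", "heatstress_units_max1", "heatstress_units_max2",
}


def parse_flat_config(lines: Iterable[str]) -> dict[str, str]:
    """Parse ``key = value`` lines; ``#`` starts a comment."""
    out: dict[str, str] = {}
    for i, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {i}: expected 'key = value', got {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        out[key] = val
    return out


def read_params_file(path: str | Path) -> SpeciesParams:
    """Read a flat ``key = value`` species parameter file.

    Unknown keys raise; omitted keys keep their defaults.
    """
    raw = parse_flat_config(Path(path).read_text().splitlines())
    kwargs: dict[str, object] = {}
    stress_kwargs: dict[str, float] = {}
    for key, val in raw.items():
        if key == "OWEventDD":  # informational: per-cohort, "varies"
            continue
        if key in _STRESS_KEYS:
            stress_kwargs[key] = float(val)
        elif key in _FLOAT_KEYS:
            kwargs[key] = float(val)
        elif key == "n_cohorts":
            kwargs[key] = int(val)
        elif key == "stgorder":
            kwargs[key] = tuple(s.strip() for s in val.split(","))
        elif key == "obligate_diapause":
            kwargs[key] = val.strip() in {"1", "true", "TRUE", "True"}
        elif key in {"distro_shape", "calctype"}:
            kwargs[key] = val.strip().strip('"')
        else:
            raise ValueError(f"unknown parameter {key!r} in {path}")
    if stress_kwargs:
        kwargs["stress"] = StressParams(**stress_kwargs)
    return SpeciesParams(**kwargs)


def write_params_file(params: SpeciesParams, path: str | Path) -> None:
    """Write the flat ``key = value`` parameter file."""
    lines = [f"{k} = {v}" for k, v in params.to_flat_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")
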