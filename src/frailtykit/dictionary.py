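"""Coding rules and the default 70-item biomarker dictionary.

A deficit dictionary maps each raw biomarker to a value on the deficit
scale: 0 means no deficit and 1 the highest level of the deficit. Three
rule kinds are supported:

``binary_range``
    0 inside a normal range (bounds inclusive), 1 outside — the usual
    coding for clinical blood chemistries.
``ordinal``
    Graded cut-points: a value maps to the level of the highest cut-point
    it reaches; below the first cut-point the deficit is 0.
``normalized``
    Min-max normalization onto [0, 1] between two reference values, with a
    direction flag saying whether high or low raw values are the deficit;
    values beyond the reference window are clamped.

The default dictionary catalogues a 23-item blood panel and a 47-item
examination panel (physical performance, cognitive, anthropometric,
spirometry, hearing/vision and cardiac domains). Its concrete cut-points
are plausible placeholders chosen so the items behave like their clinical
namesakes; they are not the cut-points of any particular study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import yaml

from .errors import DictionaryError

PANELS = ("blood", "examination")
DOMAINS = (
    "blood chemistry",
    "physical performance",
    "cognitive",
    "anthropometric",
    "spirometry",
    "hearing/vision",
    "cardiac",
)
KINDS = ("binary_range", "ordinal", "normalized")


@dataclass(frozen=True)
class CodingRule:
    """How one raw biomarker maps to a deficit value in [0, 1]."""

    item_name: str
    panel: str
    domain: str
    kind: str
    normal_range: Optional[Tuple[float, float]] = None
    cut_points: Optional[Tuple[float, ...]] = None
    levels: Optional[Tuple[float, ...]] = None
    reference_min: Optional[float] = None
    reference_max: Optional[float] = None
    direction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.panel not in PANELS:
            raise DictionaryError(f"{self.item_name}: unknown panel {self.panel!r}")
        if self.domain not in DOMAINS:
            raise DictionaryError(f"{self.item_name}: unknown domain {self.domain!r}")
        if self.kind == "binary_range":
            self._require(normal_range=True)
            lo, hi = self.normal_range  # type: ignore[misc]
            if not lo < hi:
                raise DictionaryError(
                    f"{self.item_name}: normal_range must be increasing"
                )
        elif self.kind == "ordinal":
            self._require(cut_points=True, levels=True)
            cuts = self.cut_points  # type: ignore[assignment]
            lv = self.levels  # type: ignore[assignment]
            if len(lv) != len(cuts) + 1:
                raise DictionaryError(
                    f"{self.item_name}: need one more level than cut-points"
                )
            if list(cuts) != sorted(set(cuts)):
                raise DictionaryError(f"{self.item_name}: cut-points must ascend")
            if list(lv) != sorted(set(lv)) or lv[0] != 0.0 or lv[-1] != 1.0:
                raise DictionaryError(
                    f"{self.item_name}: levels must strictly increase from 0 to 1"
                )
        elif self.kind == "normalized":
            self._require(reference_min=True, reference_max=True, direction=True)
            if not self.reference_min < self.reference_max:  # type: ignore[operator]
                raise DictionaryError(
                    f"{self.item_name}: reference_min must be < reference_max"
                )
            if self.direction not in ("higher_is_deficit", "lower_is_deficit"):
                raise DictionaryError(
                    f"{self.item_name}: unknown direction {self.direction!r}"
                )
        else:
            raise DictionaryError(f"{self.item_name}: unknown kind {self.kind!r}")

    def _require(self, **wanted: bool) -> None:
        blocks = {
            "normal_range": self.normal_range,
            "cut_points": self.cut_points,
            "levels": self.levels,
            "reference_min": self.reference_min,
            "reference_max": self.reference_max,
            "direction": self.direction,
        }
        for name, value in blocks.items():
            if wanted.get(name, False) and value is None:
                raise DictionaryError(f"{self.item_name}: {self.kind} needs {name}")
            if not wanted.get(name, False) and value is not None:
                raise DictionaryError(
                    f"{self.item_name}: {name} is not a {self.kind} parameter"
                )

    def to_dict(self) -> dict:
        d = {"item_name": self.item_name, "panel": self.panel,
             "domain": self.domain, "kind": self.kind}
        if self.kind == "binary_range":
            d["normal_range"] = list(self.normal_range)
        elif self.kind == "ordinal":
            d["cut_points"] = list(self.cut_points)
            d["levels"] = list(self.levels)
        else:
            d["reference_min"] = self.reference_min
            d["reference_max"] = self.reference_max
            d["direction"] = self.direction
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CodingRule":
        d = dict(d)
        if "normal_range" in d and d["normal_range"] is not None:
            d["normal_range"] = tuple(d["normal_range"])
        for k in ("cut_points", "levels"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


class DataDictionary:
    """An ordered collection of coding rules with unique item names."""

    def __init__(self, rules: Iterable[CodingRule]):
        self.rules: List[CodingRule] = list(rules)
        names = [r.item_name for r in self.rules]
        if len(set(names)) != len(names):
            raise DictionaryError("duplicate item names in dictionary")
        self._by_name = {r.item_name: r for r in self.rules}

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[CodingRule]:
        return iter(self.rules)

    def __contains__(self, item_name: str) -> bool:
        return item_name in self._by_name

    def __getitem__(self, item_name: str) -> CodingRule:
        try:
            return self._by_name[item_name]
        except KeyError:
            raise DictionaryError(f"no rule for item {item_name!r}") from None

    @property
    def item_names(self) -> List[str]:
        return [r.item_name for r in self.rules]

    def panel(self, panel: str) -> "DataDictionary":
        """The sub-dictionary for one panel, preserving order."""
        if panel not in PANELS:
            raise DictionaryError(f"unknown panel {panel!r}")
        return DataDictionary(r for r in self.rules if r.panel == panel)

    # ---------------------------------------------------------------- IO
    def to_records(self) -> List[dict]:
        return [r.to_dict() for r in self.rules]

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "DataDictionary":
        return cls(CodingRule.from_dict(r) for r in records)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_records(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DataDictionary":
        with open(path) as fh:
            return cls.from_records(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_records(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DataDictionary":
        with open(path) as fh:
            return cls.from_records(json.load(fh))


def _binary(name: str, lo: float, hi: float) -> CodingRule:
    return CodingRule(name, "blood", "blood chemistry", "binary_range",
                      normal_range=(lo, hi))


def _norm(name: str, domain: str, lo: float, hi: float,
          direction: str = "higher_is_deficit") -> CodingRule:
    return CodingRule(name, "examination", domain, "normalized",
                      reference_min=lo, reference_max=hi, direction=direction)


def _ordinal(name: str, domain: str, cuts: Tuple[float, ...],
             levels: Tuple[float, ...]) -> CodingRule:
    return CodingRule(name, "examination", domain, "ordinal",
                      cut_points=cuts, levels=levels)


# 23 blood biomarkers: binary normal-range rules (plausible adult reference
# intervals; out-of-range in either direction is the deficit).
_BLOOD: List[CodingRule] = [
    _binary("Red blood cell distribution width", 11.5, 14.5),     # %
    _binary("High-sensitivity C-reactive protein", 0.0, 3.0),     # mg/L
    _binary("White blood cells", 4.0, 11.0),                      # 1e9/L
    _binary("Hemoglobin A1c", 4.0, 6.0),                          # %
    _binary("Hematocrit", 0.36, 0.50),                            # L/L
    _binary("Mean corpuscular hemoglobin", 27.0, 33.0),           # pg
    _binary("Hemoglobin", 120.0, 170.0),                          # g/L
    _binary("Red blood cells", 3.8, 5.8),                         # 1e12/L
    _binary("Albumin", 35.0, 50.0),                               # g/L
    _binary("Creatinine", 50.0, 110.0),                           # umol/L
    _binary("Free thyroxine", 10.0, 22.0),                        # pmol/L
    _binary("Mean corpuscular volume", 80.0, 100.0),              # fL
    _binary("Mean platelet volume", 7.5, 11.5),                   # fL
    _binary("Cholesterol", 2.0, 5.2),                             # mmol/L
    _binary("Ferritin", 15.0, 300.0),                             # ug/L
    _binary("Triglycerides", 0.4, 1.7),                           # mmol/L
    _binary("Granulocytes", 1.5, 7.5),                            # 1e9/L
    _binary("Lymphocytes", 1.0, 4.0),                             # 1e9/L
    _binary("Monocytes", 0.2, 1.0),                               # 1e9/L
    _binary("Platelets", 150.0, 400.0),                           # 1e9/L
    _binary("25-Hydroxyvitamin D", 50.0, 250.0),                  # nmol/L
    _binary("Estimated glomerular filtration rate", 60.0, 130.0), # mL/min
    _binary("Thyroid-stimulating hormone", 0.4, 4.5),             # mIU/L
]

# 47 examination-based tests grouped by domain. Most are min-max normalized
# continuous scores; two graded instrument summaries use ordinal cut-points.
_EXAMINATION: List[CodingRule] = [
    # physical performance (5)
    _norm("Timed 4-m walk", "physical performance", 2.0, 12.0),
    _norm("Chair rise", "physical performance", 5.0, 30.0),
    _norm("Timed get up and go", "physical performance", 4.0, 25.0),
    _ordinal("Standing balance", "physical performance", (4.0, 7.0),
             (0.0, 0.5, 1.0)),  # 0-10 instability score
    _norm("Grip strength", "physical performance", 10.0, 60.0,
          "lower_is_deficit"),
    # cognitive (9)
    _norm("Stroop interference time", "cognitive", 0.0, 60.0),
    _norm("Delayed recall", "cognitive", 0.0, 15.0, "lower_is_deficit"),
    _norm("Event-based memory", "cognitive", 0.0, 10.0, "lower_is_deficit"),
    _norm("Animal fluency", "cognitive", 0.0, 35.0, "lower_is_deficit"),
    _norm("Controlled oral word association", "cognitive", 0.0, 50.0,
          "lower_is_deficit"),
    _norm("Immediate recall", "cognitive", 0.0, 15.0, "lower_is_deficit"),
    _norm("Mental alteration test", "cognitive", 0.0, 40.0,
          "lower_is_deficit"),
    _norm("Choice reaction time", "cognitive", 400.0, 1500.0),
    _norm("Time-based memory", "cognitive", 0.0, 10.0, "lower_is_deficit"),
    # anthropometric (7)
    _norm("Waist-hip ratio", "anthropometric", 0.7, 1.2),
    _norm("Body mass index", "anthropometric", 18.5, 40.0),
    _norm("Whole body BMD, T-score", "anthropometric", -4.0, 1.0,
          "lower_is_deficit"),
    _norm("BMD, multiple body regions", "anthropometric", -4.0, 1.0,
          "lower_is_deficit"),
    _norm("Appendage lean mass", "anthropometric", 10.0, 35.0,
          "lower_is_deficit"),
    _norm("Body fat percent", "anthropometric", 15.0, 50.0),
    _norm("Adiposity, multiple body regions", "anthropometric", 15.0, 50.0),
    # spirometry (2)
    _norm("Forced vital capacity (FVC)", "spirometry", 1.5, 6.0,
          "lower_is_deficit"),
    _norm("FEV 1/FVC ratio", "spirometry", 0.4, 0.9, "lower_is_deficit"),
    # hearing and vision (9)
    _norm("Hearing pure tone average, right", "hearing/vision", 0.0, 80.0),
    _norm("Hearing pure tone average, left", "hearing/vision", 0.0, 80.0),
    _norm("Visual acuity, left eye", "hearing/vision", 0.0, 1.2,
          "lower_is_deficit"),
    _norm("Visual acuity, right eye", "hearing/vision", 0.0, 1.2,
          "lower_is_deficit"),
    _norm("Intraocular pressure, right", "hearing/vision", 8.0, 30.0),
    _norm("Intraocular pressure, left", "hearing/vision", 8.0, 30.0),
    _norm("Corneal hysteresis, right", "hearing/vision", 6.0, 14.0,
          "lower_is_deficit"),
    _norm("Corneal hysteresis, left", "hearing/vision", 6.0, 14.0,
          "lower_is_deficit"),
    _norm("Mean ocular perfusion pressure", "hearing/vision", 30.0, 60.0,
          "lower_is_deficit"),
    # cardiac (15)
    _norm("Pulse", "cardiac", 50.0, 110.0),
    _norm("Max carotid intima thickness", "cardiac", 0.4, 1.5),
    _norm("ECG, QT interval", "cardiac", 350.0, 500.0),
    _norm("ECG, PQ interval", "cardiac", 120.0, 220.0),
    _norm("ECG, P axis", "cardiac", 0.0, 90.0),
    _norm("ECG, R axis", "cardiac", -30.0, 120.0),
    _norm("ECG, T axis", "cardiac", 0.0, 120.0),
    _norm("ECG, P duration", "cardiac", 60.0, 140.0),
    _norm("ECG, QRS duration", "cardiac", 70.0, 130.0),
    _ordinal("ECG diagnosis summary", "cardiac", (2.0, 4.0),
             (0.0, 0.5, 1.0)),  # 0-6 abnormality count
    _norm("Systolic BP", "cardiac", 100.0, 190.0),
    _norm("Diastolic BP", "cardiac", 60.0, 110.0),
    _norm("Pulse pressure", "cardiac", 30.0, 90.0),
    _norm("Carotid intima thickness, right", "cardiac", 0.4, 1.5),
    _norm("Carotid intima thickness, left", "cardiac", 0.4, 1.5),
]


def default_data_dictionary() -> DataDictionary:
    """The default 70-item dictionary: 23 blood + 47 examination biomarkers.

    The catalogue (names, panel and domain tags) follows the standard
    blood/examination frailty-biomarker panels; the concrete rule parameters
    are plausible placeholders, not validated clinical cut-points.
    """
    return DataDictionary(_BLOOD + _EXAMINATION)
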