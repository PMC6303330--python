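"""Radiocarbon date tables: reading, vetting, and regional/taxon filtering.

A :class:`RadiocarbonDate` is one lab measurement with the metadata needed to
vet it: lab number, measured 14C age and 1-sigma error, taxon, depositional
context, state/province, latitude, data-quality flags, and an individual
identifier used to keep a single date per dated animal.

Vetting applies the standard inclusion rules for database-derived
compilations — duplicate lab numbers, uploader-flagged anomalous dates,
non-target depositional contexts, kill/scavenging-site associations, and
one-date-per-individual deduplication — with an audit count per rule.
Removals are attributed to the first matching rule in a fixed order so the
audit is deterministic and sums exactly to the number of rows dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcurve import CalibrationCurve
from .calibrate import calibrate_date
from .errors import ArgumentError, FormatError

__all__ = [
    "RadiocarbonDate",
    "DateSet",
    "VettingRules",
    "VettingResult",
    "read_dates_csv",
    "write_dates_csv",
    "vet_dates",
    "filter_region",
    "select_taxa",
    "REGIONS",
]

_OPTIONAL_DEFAULTS = {
    "material": "",
    "taxon": "",
    "context": "",
    "state_province": "",
    "latitude": np.nan,
    "anomalous": False,
    "kill_site": False,
    "individual_id": "",
}


@dataclass(frozen=True)
class RadiocarbonDate:
    lab_id: str
    c14_age: float
    sigma_lab: float
    material: str = ""
    taxon: str = ""
    context: str = ""          # archaeological | paleontological | geological
    state_province: str = ""
    latitude: float = np.nan
    anomalous: bool = False
    kill_site: bool = False
    individual_id: str = ""


@dataclass
class DateSet:
    """A labelled collection of radiocarbon dates."""

    dates: list[RadiocarbonDate]
    label: str = ""
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.dates)

    def __iter__(self):
        return iter(self.dates)

    @property
    def c14_ages(self) -> np.ndarray:
        return np.array([d.c14_age for d in self.dates], dtype=float)

    @property
    def sigma_labs(self) -> np.ndarray:
        return np.array([d.sigma_lab for d in self.dates], dtype=float)

    def sigma_pool(self) -> np.ndarray:
        """Empirical lab-error pool for back-calibration resampling."""
        return self.sigma_labs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(d) for d in self.dates])


_REQUIRED = ("lab_id", "c14_age", "sigma_lab")


def read_dates_csv(path, label: str = "", provenance: str = "") -> DateSet:
    """Read a date table; requires lab_id, c14_age, sigma_lab columns."""
    df = pd.read_csv(path, dtype={"lab_id": str, "individual_id": str,
                                  "state_province": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    dates = []
    for i, row in df.iterrows():
        try:
            c14 = float(row["c14_age"])
            sig = float(row["sigma_lab"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {i}: unparseable numeric value") from exc
        if not np.isfinite(c14) or not np.isfinite(sig):
            raise FormatError(f"{path}: row {i}: missing numeric value")
        kwargs = {}
        for col, default in _OPTIONAL_DEFAULTS.items():
            if col in df.columns and not pd.isna(row[col]):
                val = row[col]
                if col in ("anomalous", "kill_site"):
                    val = bool(val) if isinstance(val, (bool, np.bool_)) else str(val).strip().lower() in ("1", "true", "yes")
                elif col == "latitude":
                    val = float(val)
                else:
                    val = str(val)
                kwargs[col] = val
        dates.append(RadiocarbonDate(lab_id=str(row["lab_id"]), c14_age=c14,
                                     sigma_lab=sig, **kwargs))
    return DateSet(dates=dates, label=label or str(path), provenance=provenance or str(path))


def write_dates_csv(ds: DateSet, path) -> None:
    ds.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class VettingRules:
    """Which inclusion rules to apply, and to which contexts.

    ``drop_contexts`` names depositional contexts excluded outright (for an
    anthropogenic compilation: non-cultural contexts).  ``drop_kill_sites``
    is used when vetting a paleontological megafauna set, where dates from
    kill/scavenging associations would conflate human activity with the
    taxon's own record.
    """

    drop_duplicates: bool = True
    drop_anomalous: bool = True
    drop_contexts: frozenset = frozenset({"geological"})
    drop_kill_sites: bool = False
    dedup_individuals: bool = True

    @classmethod
    def anthropogenic(cls) -> "VettingRules":
        return cls(drop_contexts=frozenset({"geological", "paleontological"}),
                   drop_kill_sites=False, dedup_individuals=False)

    @classmethod
    def megafauna(cls) -> "VettingRules":
        return cls(drop_contexts=frozenset(), drop_kill_sites=True,
                   dedup_individuals=True)


@dataclass
class VettingResult:
    dates: DateSet
    audit: dict = field(default_factory=dict)


_RULE_ORDER = ("duplicate_lab_id", "anomalous", "context", "kill_site", "duplicate_individual")


def vet_dates(ds: DateSet, rules: VettingRules = VettingRules()) -> VettingResult:
    """Apply inclusion rules; removal attributed to the first matching rule.

    Rule order: duplicates -> anomalous -> context -> kill-site -> one date
    per individual (keep first occurrence in input order for both dedups).
    """
    audit = {rule: 0 for rule in _RULE_ORDER}
    seen_labs: set[str] = set()
    seen_indiv: set[str] = set()
    kept: list[RadiocarbonDate] = []
    for d in ds.dates:
        if rules.drop_duplicates and d.lab_id in seen_labs:
            audit["duplicate_lab_id"] += 1
            continue
        seen_labs.add(d.lab_id)
        if rules.drop_anomalous and d.anomalous:
            audit["anomalous"] += 1
            continue
        if d.context in rules.drop_contexts:
            audit["context"] += 1
            continue
        if rules.drop_kill_sites and d.kill_site:
            audit["kill_site"] += 1
            continue
        if rules.dedup_individuals and d.individual_id:
            if d.individual_id in seen_indiv:
                audit["duplicate_individual"] += 1
                continue
            seen_indiv.add(d.individual_id)
        kept.append(d)
    audit["retained"] = len(kept)
    audit["input"] = len(ds)
    out = DateSet(dates=kept, label=ds.label, provenance=ds.provenance)
    return VettingResult(dates=out, audit=audit)


# Southwest: CA/NV/UT/AZ/NM. Great Lakes: every state or province bordering
# any of the Great Lakes. The contiguous-US compilation uses a latitude cut.
REGIONS = {
    "southwest": frozenset({"CA", "NV", "UT", "AZ", "NM"}),
    "great_lakes": frozenset({"ON", "NY", "PA", "OH", "MI", "IN", "IL", "WI", "MN"}),
}

_NAME_TO_CODE = {
    "california": "CA", "nevada": "NV", "utah": "UT", "arizona": "AZ",
    "new mexico": "NM", "ontario": "ON", "new york": "NY",
    "pennsylvania": "PA", "ohio": "OH", "michigan": "MI", "indiana": "IN",
    "illinois": "IL", "wisconsin": "WI", "minnesota": "MN",
}


def _state_code(value: str) -> str:
    v = value.strip()
    if len(v) == 2:
        return v.upper()
    return _NAME_TO_CODE.get(v.lower(), v.upper())


def filter_region(ds: DateSet, region: str) -> DateSet:
    """Restrict a date set to one of the named study regions.

    ``southwest`` and ``great_lakes`` match on state/province;
    ``contiguous_us`` keeps dates south of 52 degrees N latitude.
    """
    if region == "contiguous_us":
        kept = [d for d in ds.dates
                if np.isfinite(d.latitude) and d.latitude < 52.0]
    elif region in REGIONS:
        members = REGIONS[region]
        kept = [d for d in ds.dates
                if d.state_province and _state_code(d.state_province) in members]
    else:
        raise ArgumentError(
            f"unknown region {region!r}; expected southwest, great_lakes or contiguous_us"
        )
    return DateSet(dates=kept, label=f"{ds.label}[{region}]", provenance=ds.provenance)


def select_taxa(
    ds: DateSet,
    curve: CalibrationCurve,
    window,
    min_dates: int = 20,
) -> dict[str, DateSet]:
    """Per-taxon date sets for taxa with strictly more than ``min_dates``
    dates whose modal calibrated year falls inside ``window``.

    Window membership is decided by the mode of each date's calibrated
    density — the simplest reproducible assignment of a date to a period.
    """
    if min_dates < 1:
        raise ArgumentError("min_dates must be >= 1")
    old, young = max(window), min(window)
    by_taxon: dict[str, list[RadiocarbonDate]] = {}
    for d in ds.dates:
        if not d.taxon:
            continue
        mode = calibrate_date(d.c14_age, d.sigma_lab, curve).mode_year()
        if young <= mode <= old:
            by_taxon.setdefault(d.taxon, []).append(d)
    return {
        taxon: DateSet(dates=dd, label=f"{ds.label}[{taxon}]", provenance=ds.provenance)
        for taxon, dd in sorted(by_taxon.items())
        if len(dd) > min_dates
    }
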