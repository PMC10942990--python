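"""Reading HMD period death-rate files and assembling the joint panel.

The Human Mortality Database publishes central death rates m_x as
whitespace-separated ``Mx_1x1`` text files: a one-line preamble, a blank
line, the header ``Year Age Female Male Total`` and one record per
(year, age) with missing values printed as ``.`` and the open age interval
written ``110+``. Users supply these files themselves (HMD is
registration-gated); everything downstream works equally from the synthetic
generator, which writes the same dialect.

The joint object is :class:`MortalityPanel`: an m-country x T-year x d-age
array of natural-log death rates. Cells missing (or non-positive, where the
log is undefined) in one country are imputed with the mean raw rate of the
remaining countries at the same (year, age) before the log transform, and
flagged in ``imputed_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "MxParseError", "MortalitySurface", "CountryRegistry", "MortalityPanel",
    "read_hmd_mx", "write_hmd_mx", "build_panel", "split_train_test",
    "load_default_registry",
]

_SEX_COLUMNS = {"female": 2, "male": 3, "total": 4}
OPEN_AGE = 110


class MxParseError(ValueError):
    """Structured parse failure naming the offending file line."""

    def __init__(self, path, line_no: int, message: str):
        self.path, self.line_no = str(path), line_no
        super().__init__(f"{path}:{line_no}: {message}")


@dataclass
class MortalitySurface:
    """One country's year x age grid of central death rates.

    ``rates`` holds NaN where the source value was missing. Ages run over
    whatever the file provides (0..110 with the open interval stored as the
    integer 110); trimming to the modelling range happens in
    :func:`build_panel`.
    """

    country_code: str
    years: np.ndarray
    ages: np.ndarray
    rates: np.ndarray
    sex_channel: str = "total"

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.ages = np.asarray(self.ages, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.sex_channel not in _SEX_COLUMNS:
            raise ValueError(f"unknown sex channel {self.sex_channel!r}")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be strictly increasing and consecutive")
        if self.rates.shape != (len(self.years), len(self.ages)):
            raise ValueError(
                f"rates shape {self.rates.shape} does not match "
                f"{len(self.years)} years x {len(self.ages)} ages"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.rates < 0):
                raise ValueError("negative death rates are not valid")


@dataclass(frozen=True)
class Country:
    code: str
    name: str
    capital_lat: float
    capital_lon: float


@dataclass
class CountryRegistry:
    """Capital coordinates per country, keyed by HMD-style code."""

    countries: dict[str, Country] = field(default_factory=dict)

    def add(self, code: str, name: str, lat: float, lon: float) -> None:
        if code in self.countries:
            raise ValueError(f"duplicate country code {code!r}")
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"coordinates out of range for {code!r}: {lat}, {lon}")
        self.countries[code] = Country(code, name, lat, lon)

    def __contains__(self, code: str) -> bool:
        return code in self.countries

    def __getitem__(self, code: str) -> Country:
        return self.countries[code]

    def codes(self) -> list[str]:
        return sorted(self.countries)

    @classmethod
    def from_tsv(cls, path) -> "CountryRegistry":
        reg = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code, name, lat, lon = line.split("\t")
            reg.add(code, name, float(lat), float(lon))
        return reg


def load_default_registry() -> CountryRegistry:
    """Capitals of the 16 European countries with full 1950-2016 coverage."""
    with resources.as_file(
        resources.files("mortgraph.data").joinpath("capitals.tsv")
    ) as path:
        return CountryRegistry.from_tsv(path)


@dataclass
class MortalityPanel:
    """Aligned multi-country log-mortality array.

    ``log_rates`` has shape (m, T_L, d); ``imputed_mask`` is True exactly
    where the source rate was missing or non-positive and the value was
    filled with the cross-country mean.
    """

    countries: list[str]
    years: np.ndarray
    ages: np.ndarray
    log_rates: np.ndarray
    imputed_mask: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.ages = np.asarray(self.ages, dtype=int)
        self.log_rates = np.asarray(self.log_rates, dtype=float)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        expect = (len(self.countries), len(self.years), len(self.ages))
        if self.log_rates.shape != expect:
            raise ValueError(f"log_rates shape {self.log_rates.shape} != {expect}")
        if self.imputed_mask.shape != expect:
            raise ValueError("imputed_mask shape mismatch")
        if not np.all(np.isfinite(self.log_rates)):
            raise ValueError("log_rates must be finite after imputation")

    @property
    def m(self) -> int:
        return len(self.countries)

    @property
    def T_L(self) -> int:
        return len(self.years)

    @property
    def d(self) -> int:
        return len(self.ages)

    def country_matrix(self, code: str) -> np.ndarray:
        return self.log_rates[self.countries.index(code)]


# ----------------------------------------------------------------------
# HMD Mx_1x1 dialect
# ----------------------------------------------------------------------

def _parse_age(token: str, path, line_no: int) -> int:
    if token.endswith("+"):
        token = token[:-1]
    try:
        return int(token)
    except ValueError:
        raise MxParseError(path, line_no, f"unparsable age token {token!r}") from None


def _parse_rate(token: str) -> float:
    if token == ".":
        return np.nan
    try:
        value = float(token)
    except ValueError:
        return np.nan  # unparsable numerics become missing, per the dialect
    return value if value >= 0 else np.nan


def read_hmd_mx(path, sex_channel: str = "total",
                country_code: str | None = None) -> MortalitySurface:
    """Parse one HMD ``Mx_1x1`` file into a :class:`MortalitySurface`.

    ``country_code`` defaults to the file stem up to the first dot
    (``SWE.Mx_1x1.txt`` -> ``SWE``).
    """
    if sex_channel not in _SEX_COLUMNS:
        raise ValueError(f"unknown sex channel {sex_channel!r}")
    path = Path(path)
    if country_code is None:
        country_code = path.name.split(".")[0]
    col = _SEX_COLUMNS[sex_channel]

    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise MxParseError(path, 0, f"unreadable file: {exc}") from exc

    records: dict[int, dict[int, float]] = {}
    header_seen = False
    last_year = None
    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if not header_seen:
            if fields[0] == "Year":
                if fields[:5] != ["Year", "Age", "Female", "Male", "Total"]:
                    raise MxParseError(path, line_no,
                                       f"unexpected header {fields[:5]}")
                header_seen = True
            continue  # preamble lines before the header
        if len(fields) != 5:
            raise MxParseError(
                path, line_no, f"expected 5 fields, found {len(fields)}"
            )
        try:
            year = int(fields[0])
        except ValueError:
            raise MxParseError(path, line_no,
                               f"unparsable year {fields[0]!r}") from None
        age = _parse_age(fields[1], path, line_no)
        if last_year is not None and year < last_year:
            raise MxParseError(path, line_no,
                               f"years not monotone: {year} after {last_year}")
        last_year = year
        records.setdefault(year, {})[age] = _parse_rate(fields[col])

    if not header_seen:
        raise MxParseError(path, 0, "no 'Year Age Female Male Total' header found")
    if not records:
        raise MxParseError(path, 0, "no data records found")

    years = np.array(sorted(records), dtype=int)
    ages = np.array(sorted({a for r in records.values() for a in r}), dtype=int)
    rates = np.full((len(years), len(ages)), np.nan)
    age_index = {a: j for j, a in enumerate(ages)}
    for i, year in enumerate(years):
        for age, rate in records[year].items():
            rates[i, age_index[age]] = rate
    return MortalitySurface(country_code, years, ages, rates, sex_channel)


def write_hmd_mx(surface: MortalitySurface, path,
                 preamble: str | None = None) -> None:
    """Write a surface in the ``Mx_1x1`` dialect (round-trips with the reader).

    The requested sex channel is written into its own column; the other two
    columns are printed as missing.
    """
    path = Path(path)
    col = _SEX_COLUMNS[surface.sex_channel]
    lines = [preamble or f"{surface.country_code}, Mx (period 1x1)", ""]
    lines.append("  Year          Age             Female            Male           Total")
    for i, year in enumerate(surface.years):
        for j, age in enumerate(surface.ages):
            age_tok = f"{age}+" if age == OPEN_AGE else str(age)
            rate = surface.rates[i, j]
            # shortest repr that round-trips to the same float64
            tok = "." if np.isnan(rate) else np.format_float_positional(
                rate, trim="-"
            )
            fields = ["."] * 3
            fields[col - 2] = tok
            lines.append(f"  {year}    {age_tok:>5}    {fields[0]:>16} "
                         f"{fields[1]:>16} {fields[2]:>16}")
    path.write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Panel assembly
# ----------------------------------------------------------------------

def build_panel(surfaces: list[MortalitySurface],
                year_range: tuple[int, int] = (1950, 2016),
                age_range: tuple[int, int] = (0, 100)) -> MortalityPanel:
    """Trim, align, impute and log-transform the surfaces into one panel.

    Non-positive rates are treated as missing (their log is undefined) and
    imputed, on the raw-rate scale, with the mean rate of all other
    countries at the same (year, age). Countries are ordered alphabetically
    by code so matrix axes are reproducible.
    """
    if len(surfaces) < 2:
        raise ValueError("need at least 2 surfaces to build a panel")
    y0, y1 = year_range
    a0, a1 = age_range
    years = np.arange(y0, y1 + 1)
    ages = np.arange(a0, a1 + 1)

    surfaces = sorted(surfaces, key=lambda s: s.country_code)
    codes = [s.country_code for s in surfaces]
    raw = np.full((len(surfaces), len(years), len(ages)), np.nan)
    for i, surf in enumerate(surfaces):
        if surf.years[0] > y0 or surf.years[-1] < y1:
            raise ValueError(
                f"{surf.country_code}: years {surf.years[0]}-{surf.years[-1]} "
                f"do not cover {y0}-{y1}"
            )
        ysel = np.searchsorted(surf.years, years)
        asel = np.searchsorted(surf.ages, ages)
        if not np.array_equal(surf.ages[asel], ages):
            raise ValueError(f"{surf.country_code}: ages do not cover {a0}-{a1}")
        raw[i] = surf.rates[np.ix_(ysel, asel)]

    with np.errstate(invalid="ignore"):
        raw[raw <= 0] = np.nan  # log undefined: treat as missing
    mask = np.isnan(raw)
    if mask.any():
        col_sum = np.nansum(raw, axis=0)
        col_cnt = (~mask).sum(axis=0)
        dead = col_cnt == 0
        if dead.any():
            yy, aa = np.argwhere(dead)[0]
            raise ValueError(
                f"cell (year={years[yy]}, age={ages[aa]}) missing in all "
                "countries; imputation impossible"
            )
        # a missing cell contributes nothing to col_sum, so the mean over
        # countries with data IS the mean of the other countries
        fill = col_sum[None] / col_cnt[None]
        raw = np.where(mask, fill, raw)

    return MortalityPanel(codes, years, ages, np.log(raw), mask)


def split_train_test(panel: MortalityPanel,
                     last_train_year: int = 2000
                     ) -> tuple[MortalityPanel, MortalityPanel]:
    """Partition the panel's years into a train block and a test block."""
    if not (panel.years[0] < last_train_year < panel.years[-1]):
        raise ValueError(
            f"last_train_year={last_train_year} must lie strictly inside "
            f"{panel.years[0]}-{panel.years[-1]}"
        )
    cut = int(np.searchsorted(panel.years, last_train_year, side="right"))
    train = replace(
        panel,
        years=panel.years[:cut],
        log_rates=panel.log_rates[:, :cut],
        imputed_mask=panel.imputed_mask[:, :cut],
    )
    test = replace(
        panel,
        years=panel.years[cut:],
        log_rates=panel.log_rates[:, cut:],
        imputed_mask=panel.imputed_mask[:, cut:],
    )
    return train, test
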