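"""Country code handling.

Canonical country identifiers throughout the package are ISO 3166-1
alpha-3 codes ("ISO3").  FAOSTAT trade matrices report country *names*,
so a name -> ISO3 lookup for the names that actually occur in FAOSTAT
exports ships here.  Unrecognised names that already look like ISO3
codes (three ASCII capitals) pass through unchanged; anything else
raises, because silently inventing a code corrupts bilateral netting.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: ISO 3166-1 alpha-3 codes used to label synthetic countries.  Order is
#: stable so that seeded world generation is reproducible.
ISO3_CODES: tuple[str, ...] = (
    "AFG", "ALB", "DZA", "AGO", "ARG", "ARM", "AUS", "AUT", "AZE", "BGD",
    "BLR", "BEL", "BEN", "BTN", "BOL", "BIH", "BWA", "BRA", "BRN", "BGR",
    "BFA", "BDI", "KHM", "CMR", "CAN", "CPV", "CAF", "TCD", "CHL", "CHN",
    "COL", "COM", "COG", "COD", "CRI", "CIV", "HRV", "CUB", "CYP", "CZE",
    "DNK", "DJI", "DOM", "ECU", "EGY", "SLV", "GNQ", "ERI", "EST", "ETH",
    "FJI", "FIN", "FRA", "GAB", "GMB", "GEO", "DEU", "GHA", "GRC", "GTM",
    "GIN", "GNB", "GUY", "HTI", "HND", "HUN", "ISL", "IND", "IDN", "IRN",
    "IRQ", "IRL", "ISR", "ITA", "JAM", "JPN", "JOR", "KAZ", "KEN", "KIR",
    "PRK", "KOR", "KWT", "KGZ", "LAO", "LVA", "LBN", "LSO", "LBR", "LBY",
    "LTU", "LUX", "MKD", "MDG", "MWI", "MYS", "MDV", "MLI", "MLT", "MRT",
    "MUS", "MEX", "MDA", "MNG", "MNE", "MAR", "MOZ", "MMR", "NAM", "NPL",
    "NLD", "NZL", "NIC", "NER", "NGA", "NOR", "OMN", "PAK", "PAN", "PNG",
    "PRY", "PER", "PHL", "POL", "PRT", "QAT", "ROU", "RUS", "RWA", "WSM",
    "STP", "SAU", "SEN", "SRB", "SYC", "SLE", "SGP", "SVK", "SVN", "SLB",
    "SOM", "ZAF", "SSD", "ESP", "LKA", "SDN", "SUR", "SWE", "CHE", "SYR",
    "TJK", "TZA", "THA", "TLS", "TGO", "TON", "TTO", "TUN", "TUR", "TKM",
    "UGA", "UKR", "ARE", "GBR", "USA", "URY", "UZB", "VUT", "VEN", "VNM",
    "YEM", "ZMB", "ZWE", "BHS", "BHR", "BRB", "BLZ", "DMA", "GRD", "LCA",
    "VCT", "ATG", "KNA", "SWZ", "PLW", "MHL", "FSM", "NRU", "TUV", "AND",
    "MCO", "SMR", "LIE", "HKG", "MAC", "TWN", "PSE", "NCL", "PYF", "ABW",
    "CUW", "GRL", "FRO", "BMU", "CYM", "GIB", "FLK", "GUM", "ASM", "COK",
    "NIU", "TKL", "WLF", "MSR", "AIA", "VGB", "TCA", "SPM", "SHN", "REU",
    "GLP", "MTQ", "GUF", "MYT",
)

#: FAOSTAT reporter/partner names -> ISO3.  Covers the names whose
#: FAOSTAT spelling differs from the plain English country name, plus
#: the high-volume traders; extend via `CountrySet.aliases`.
FAOSTAT_NAME_TO_ISO3: dict[str, str] = {
    "Afghanistan": "AFG", "Albania": "ALB", "Algeria": "DZA",
    "Argentina": "ARG", "Australia": "AUS", "Austria": "AUT",
    "Bangladesh": "BGD", "Belarus": "BLR", "Belgium": "BEL",
    "Belgium-Luxembourg": "BEL", "Bolivia (Plurinational State of)": "BOL",
    "Brazil": "BRA", "Bulgaria": "BGR", "Cambodia": "KHM",
    "Canada": "CAN", "Chile": "CHL", "China": "CHN",
    "China, mainland": "CHN", "China, Hong Kong SAR": "HKG",
    "China, Macao SAR": "MAC", "China, Taiwan Province of": "TWN",
    "Colombia": "COL", "Costa Rica": "CRI", "Croatia": "HRV",
    "Cuba": "CUB", "Czechia": "CZE", "Czech Republic": "CZE",
    "Côte d'Ivoire": "CIV", "Democratic People's Republic of Korea": "PRK",
    "Democratic Republic of the Congo": "COD", "Denmark": "DNK",
    "Ecuador": "ECU", "Egypt": "EGY", "Estonia": "EST",
    "Ethiopia": "ETH", "Finland": "FIN", "France": "FRA",
    "Germany": "DEU", "Ghana": "GHA", "Greece": "GRC",
    "Guatemala": "GTM", "Hungary": "HUN", "India": "IND",
    "Indonesia": "IDN", "Iran (Islamic Republic of)": "IRN",
    "Iraq": "IRQ", "Ireland": "IRL", "Israel": "ISR", "Italy": "ITA",
    "Japan": "JPN", "Jordan": "JOR", "Kazakhstan": "KAZ",
    "Kenya": "KEN", "Lao People's Democratic Republic": "LAO",
    "Latvia": "LVA", "Lithuania": "LTU", "Malaysia": "MYS",
    "Mexico": "MEX", "Morocco": "MAR", "Myanmar": "MMR",
    "Netherlands": "NLD", "Netherlands (Kingdom of the)": "NLD",
    "New Zealand": "NZL", "Nigeria": "NGA", "Norway": "NOR",
    "Pakistan": "PAK", "Paraguay": "PRY", "Peru": "PER",
    "Philippines": "PHL", "Poland": "POL", "Portugal": "PRT",
    "Qatar": "QAT", "Republic of Korea": "KOR",
    "Republic of Moldova": "MDA", "Romania": "ROU",
    "Russian Federation": "RUS", "Saudi Arabia": "SAU",
    "Senegal": "SEN", "Serbia": "SRB", "Singapore": "SGP",
    "Slovakia": "SVK", "Slovenia": "SVN", "South Africa": "ZAF",
    "Spain": "ESP", "Sri Lanka": "LKA", "Sudan": "SDN",
    "Sweden": "SWE", "Switzerland": "CHE",
    "Syrian Arab Republic": "SYR", "Thailand": "THA", "Tunisia": "TUN",
    "Turkey": "TUR", "Türkiye": "TUR", "Ukraine": "UKR",
    "United Arab Emirates": "ARE",
    "United Kingdom of Great Britain and Northern Ireland": "GBR",
    "United Kingdom": "GBR", "United Republic of Tanzania": "TZA",
    "United States of America": "USA", "United States": "USA",
    "Uruguay": "URY", "Uzbekistan": "UZB",
    "Venezuela (Bolivarian Republic of)": "VEN", "Viet Nam": "VNM",
    "Vietnam": "VNM", "Yemen": "YEM", "Zambia": "ZMB", "Zimbabwe": "ZWE",
}


class UnknownCountryError(KeyError):
    """A country name could not be resolved to an ISO3 code."""


def to_iso3(name: str, aliases: dict[str, str] | None = None) -> str:
    """Resolve a country name (or pass through an ISO3 code) to ISO3."""
    name = name.strip()
    if aliases and name in aliases:
        return aliases[name]
    if name in FAOSTAT_NAME_TO_ISO3:
        return FAOSTAT_NAME_TO_ISO3[name]
    if len(name) == 3 and name.isalpha() and name.isupper():
        return name
    raise UnknownCountryError(
        f"cannot resolve country name {name!r} to an ISO3 code; "
        "pass an alias mapping or use ISO3 codes directly"
    )


def synthetic_codes(n: int) -> list[str]:
    """`n` stable country labels: real ISO3 codes, then S00, S01, ..."""
    if n <= len(ISO3_CODES):
        return list(ISO3_CODES[:n])
    extra = [f"S{i:02d}" for i in range(n - len(ISO3_CODES))]
    return list(ISO3_CODES) + extra


@dataclass
class CountrySet:
    """The countries of a world plus optional region/adjacency metadata.

    ``adjacency`` maps an unordered country pair (stored sorted) to a
    great-circle-ish distance in km; ``adjacent_km`` is the threshold
    below which a pair counts as adjacent (sharing a border is modelled
    as small distance).  A plain boolean adjacency table is expressed by
    distance 0 for adjacent pairs.
    """

    codes: set[str]
    region_map: dict[str, str] = field(default_factory=dict)
    adjacency: dict[tuple[str, str], float] = field(default_factory=dict)
    adjacent_km: float = 500.0
    aliases: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def distance(self, a: str, b: str) -> float | None:
        return self.adjacency.get(self._key(a, b))

    def is_adjacent(self, a: str, b: str) -> bool | None:
        d = self.distance(a, b)
        return None if d is None else d <= self.adjacent_km

    def validate_trade(self, countries) -> None:
        missing = {c for c in countries} - self.codes
        if missing:
            raise UnknownCountryError(
                f"trade references countries absent from the country set: "
                f"{sorted(missing)[:10]}"
            )
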