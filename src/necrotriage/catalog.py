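"""Feature catalog: the dictionary of candidate clinical parameters.

The candidate predictors form three groups: patient age (``f0``), the
complete-blood-count ("blood routine") panel (``f1``-``f20``) and the
liver/kidney serum-chemistry panel (``f21``-``f50``).  Three analysis
designs are built on top of these panels:

* ``M1`` -- blood-routine panel only,
* ``M2`` -- liver/kidney panel only,
* ``M3`` -- both panels.

Whether age joins a design is configurable (``include_age_in``); by
default it is offered to all three.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Panel",
    "Design",
    "CatalogEntry",
    "FeatureCatalog",
    "normalize_name",
    "DEFAULT_INCLUDE_AGE_IN",
]


class Panel(str, enum.Enum):
    """Examination panel a feature belongs to."""

    AGE = "age"
    BLOOD_ROUTINE = "blood_routine"
    LIVER_KIDNEY = "liver_kidney"


class Design(str, enum.Enum):
    """Analysis design: which panels are in play."""

    M1 = "M1"  # blood routine only
    M2 = "M2"  # liver/kidney only
    M3 = "M3"  # both panels

    @classmethod
    def coerce(cls, value: "Design | str") -> "Design":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


#: designs that include the age feature by default
DEFAULT_INCLUDE_AGE_IN: tuple[Design, ...] = (Design.M1, Design.M2, Design.M3)

_PANELS_FOR_DESIGN = {
    Design.M1: (Panel.BLOOD_ROUTINE,),
    Design.M2: (Panel.LIVER_KIDNEY,),
    Design.M3: (Panel.BLOOD_ROUTINE, Panel.LIVER_KIDNEY),
}

_ID_RE = re.compile(r"^f(\d{1,2})$")


def normalize_name(name: str) -> str:
    """Case/hyphen-insensitive canonical form of a feature name."""
    s = name.strip().lower().replace("-", " ")
    return re.sub(r"\s+", " ", s)


@dataclass(frozen=True)
class CatalogEntry:
    feature_id: str
    name: str
    panel: Panel
    precision: int  # decimal places used when binning values for the mode


class FeatureCatalog:
    """The 51-entry feature dictionary shared by every pipeline stage.

    Parameters
    ----------
    entries:
        Exactly 51 :class:`CatalogEntry` rows: ``f0`` with panel ``age``,
        ``f1``-``f20`` blood routine, ``f21``-``f50`` liver/kidney.
    """

    N_FEATURES = 51

    def __init__(self, entries: Sequence[CatalogEntry]):
        entries = list(entries)
        if len(entries) != self.N_FEATURES:
            raise ValueError(
                f"catalog must have exactly {self.N_FEATURES} entries, got {len(entries)}"
            )
        ids = [e.feature_id for e in entries]
        expected = [f"f{i}" for i in range(self.N_FEATURES)]
        if ids != expected:
            raise ValueError("feature ids must be f0..f50 in order")
        norm = [normalize_name(e.name) for e in entries]
        if len(set(norm)) != len(norm):
            raise ValueError("feature names must be unique after normalization")
        for e in entries:
            idx = int(_ID_RE.match(e.feature_id).group(1))
            want = (
                Panel.AGE if idx == 0 else Panel.BLOOD_ROUTINE if idx <= 20 else Panel.LIVER_KIDNEY
            )
            if e.panel is not want:
                raise ValueError(f"{e.feature_id} must have panel {want.value}, got {e.panel.value}")
            if e.precision < 0:
                raise ValueError("precision must be >= 0")
        self.entries: tuple[CatalogEntry, ...] = tuple(entries)
        self._by_id = {e.feature_id: e for e in entries}
        self._by_norm_name = {normalize_name(e.name): e for e in entries}

    # -- construction -------------------------------------------------

    @classmethod
    def default(cls) -> "FeatureCatalog":
        """The packaged catalog."""
        with resources.files("necrotriage.data").joinpath("feature_catalog.csv").open(
            "r", encoding="utf-8"
        ) as fh:
            df = pd.read_csv(fh)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureCatalog":
        entries = [
            CatalogEntry(
                feature_id=str(r.feature_id),
                name=str(r.name_),
                panel=Panel(str(r.panel)),
                precision=int(r.precision),
            )
            for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
        ]
        return cls(entries)

    # -- lookup -------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def entry(self, feature_id: str) -> CatalogEntry:
        try:
            return self._by_id[feature_id]
        except KeyError:
            raise KeyError(f"unknown feature id {feature_id!r}") from None

    def precision(self, feature_id: str) -> int:
        return self.entry(feature_id).precision

    def name_of(self, feature_id: str) -> str:
        return self.entry(feature_id).name

    def id_for_name(self, name: str) -> str:
        """Resolve a feature name (case/hyphen-insensitively) to its id."""
        try:
            return self._by_norm_name[normalize_name(name)].feature_id
        except KeyError:
            raise KeyError(f"unknown feature name {name!r}") from None

    def resolve(self, token: str) -> str:
        """Accept either a feature id or a feature name; return the id."""
        if token in self._by_id:
            return token
        return self.id_for_name(token)

    def catalog_order(self, feature_ids: Iterable[str]) -> list[str]:
        """Sort the given ids into catalog (f0..f50) order."""
        order = {fid: i for i, fid in enumerate(self.feature_ids)}
        return sorted(feature_ids, key=lambda f: order[f])

    # -- designs ------------------------------------------------------

    def design_feature_ids(
        self,
        design: Design | str,
        include_age_in: Sequence[Design] = DEFAULT_INCLUDE_AGE_IN,
    ) -> list[str]:
        """Feature ids belonging to a design, in catalog order."""
        design = Design.coerce(design)
        panels = set(_PANELS_FOR_DESIGN[design])
        ids = [e.feature_id for e in self.entries if e.panel in panels]
        if design in tuple(Design.coerce(d) for d in include_age_in):
            ids = ["f0"] + ids
        return self.catalog_order(ids)
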