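"""Fatty-acid identities, molar masses and composition-table arithmetic.

Fatty acids are named with the shorthand ``C:Dn-x`` used in lipid
nutrition (carbons : double bonds, omega series), e.g. ``18:3n-3`` for
alpha-linolenic acid (ALA) or ``22:6n-3`` for docosahexaenoic acid
(DHA).  Composition tables report each acid as a percent of total fatty
acids within a matrix (feed, muscle, liver, carcass, faeces), together
with the total fatty-acid content of the lipid (mg g^-1 lipid), the
lipid fraction of the dry matter and the dry-matter fraction of the
as-is material.  Those three scalars bridge relative composition to
absolute contents and to moles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "FattyAcid",
    "FAProfile",
    "parse_shorthand",
    "molar_mass",
    "absolute_content",
    "composition_ratios",
    "is_class_label",
    "COMMON_NAMES",
]

# Atomic masses (g mol^-1), CODATA-style values rounded to published precision.
_MASS_C = 12.011
_MASS_H = 1.008
_MASS_O = 15.999

_SHORTHAND_RE = re.compile(r"^(\d+):(\d+)(?:n-(\d+))?$")

#: Common names for the acids discussed in oil-blend feeding trials.
COMMON_NAMES: dict[str, str] = {
    "16:0": "PA",
    "18:1n-9": "OA",
    "18:2n-6": "LA",
    "20:4n-6": "ARA",
    "18:3n-3": "ALA",
    "18:4n-3": "SDA",
    "20:4n-3": "ETA",
    "20:5n-3": "EPA",
    "22:5n-3": "DPA",
    "22:6n-3": "DHA",
}

#: Lumped class labels carried through composition tables.  They join sums
#: and ratios but have no molecular identity, so they never enter molar
#: conversions or the bioconversion pathway.
CLASS_LABELS = frozenset(
    {
        "Other SFA",
        "Total SFA",
        "Other MUFA",
        "Total MUFA",
        "Other n-6 PUFA",
        "Total n-6 PUFA",
        "Other n-3 PUFA",
        "Total n-3 LC PUFA",
        "Total n-3 PUFA",
        "Total PUFA",
    }
)


class FattyAcidParseError(ValueError):
    """Raised when a token cannot be read as ``C:Dn-x`` shorthand."""


def is_class_label(text: str) -> bool:
    """True if *text* denotes a lumped class ("Other SFA", ...) rather
    than an individual fatty acid."""
    return text in CLASS_LABELS or (
        not _SHORTHAND_RE.match(text.strip()) and any(w in text for w in ("SFA", "MUFA", "PUFA"))
    )


@dataclass(frozen=True, order=True)
class FattyAcid:
    """A fatty acid identified by carbon count, double bonds and omega series.

    ``omega_series`` is ``"n-3"``, ``"n-6"`` etc., or ``None`` for
    saturates.  Instances are immutable, hashable and usable as mapping
    keys in composition tables.
    """

    carbons: int
    double_bonds: int
    omega_series: str | None = None

    def __post_init__(self) -> None:
        if self.carbons < 4:
            raise ValueError(f"carbons must be >= 4, got {self.carbons}")
        if not 0 <= self.double_bonds < self.carbons:
            raise ValueError(
                f"double bonds must lie in [0, carbons), got {self.double_bonds}"
            )
        if self.double_bonds == 0 and self.omega_series is not None:
            raise ValueError("a saturated fatty acid has no omega series")

    @property
    def shorthand(self) -> str:
        base = f"{self.carbons}:{self.double_bonds}"
        return base if self.omega_series is None else f"{base}{self.omega_series}"

    @property
    def label(self) -> str | None:
        """Common name (ALA, EPA, DHA, ...) when one exists."""
        return COMMON_NAMES.get(self.shorthand)

    @property
    def molar_mass(self) -> float:
        return molar_mass(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.shorthand


def parse_shorthand(text: str) -> FattyAcid:
    """Parse ``"C:Dn-x"`` shorthand into a :class:`FattyAcid`.

    Lumped class labels ("Other SFA") are not fatty acids; use
    :func:`is_class_label` to screen them first.

    >>> parse_shorthand("22:6n-3")
    FattyAcid(carbons=22, double_bonds=6, omega_series='n-3')
    """
    token = text.strip()
    m = _SHORTHAND_RE.match(token)
    if not m:
        raise FattyAcidParseError(f"not a fatty-acid shorthand: {token!r}")
    carbons, dbonds = int(m.group(1)), int(m.group(2))
    series = f"n-{m.group(3)}" if m.group(3) else None
    try:
        return FattyAcid(carbons, dbonds, series)
    except ValueError as exc:
        raise FattyAcidParseError(f"invalid fatty acid {token!r}: {exc}") from exc


def molar_mass(fa: FattyAcid) -> float:
    """Molar mass (g mol^-1) of the free fatty acid CnH(2n-2d)O2.

    Balance methods report free-acid moles even though GC quantifies
    methyl esters; the free-acid mass is used throughout.
    """
    n, d = fa.carbons, fa.double_bonds
    return _MASS_C * n + _MASS_H * (2 * n - 2 * d) + 2 * _MASS_O


def _as_key(fa: "FattyAcid | str") -> str:
    if isinstance(fa, FattyAcid):
        return fa.shorthand
    return fa


@dataclass
class FAProfile:
    """Fatty-acid composition of one matrix with its content metadata.

    Parameters
    ----------
    matrix_label:
        Free-text label, e.g. ``"TOFX feed"`` or ``"FO muscle"``.
    composition:
        Percent of total fatty acids per entry (0-100).  Keys are
        shorthand strings or class labels; :class:`FattyAcid` keys are
        accepted and normalised to shorthand.
    total_fa_content:
        mg fatty acid per g lipid.
    lipid_content:
        g lipid per g dry matter.
    dry_matter:
        g dry matter per g as-is material.
    """

    matrix_label: str
    composition: dict[str, float] = field(default_factory=dict)
    total_fa_content: float | None = None
    lipid_content: float | None = None
    dry_matter: float | None = None

    def __post_init__(self) -> None:
        self.composition = { _as_key(k): float(v) for k, v in self.composition.items() }
        for k, v in self.composition.items():
            if v < 0:
                raise ValueError(f"negative percent for {k!r} in {self.matrix_label!r}")
        if self.total_fa_content is not None and not 0 < self.total_fa_content <= 1000:
            raise ValueError("total_fa_content must lie in (0, 1000] mg g^-1 lipid")
        for name in ("lipid_content", "dry_matter"):
            v = getattr(self, name)
            if v is not None and not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1] g g^-1")

    def percent(self, fa: "FattyAcid | str") -> float:
        """Percent of total FA for an acid or class; 0 if absent."""
        return self.composition.get(_as_key(fa), 0.0)

    def individual_acids(self) -> list[FattyAcid]:
        """Parsed individual fatty acids, excluding lumped classes."""
        out = []
        for k in self.composition:
            if not is_class_label(k):
                try:
                    out.append(parse_shorthand(k))
                except FattyAcidParseError:
                    continue
        return out

    def series_total(self, series: str, exclude_totals: bool = True) -> float:
        """Sum of percents over one omega series, including its 'Other'
        class entry but not 'Total ...' roll-ups."""
        total = 0.0
        for k, v in self.composition.items():
            if is_class_label(k):
                if k.startswith("Other") and k.endswith(f"{series} PUFA"):
                    total += v
                continue
            try:
                fa = parse_shorthand(k)
            except FattyAcidParseError:
                continue
            if fa.omega_series == series:
                total += v
        return total


def absolute_content(
    profile: FAProfile,
    fa: "FattyAcid | str",
    basis: str = "per g DM",
) -> float:
    """Absolute content (mg) of one acid or class on the requested basis.

    ``basis`` is one of ``"per g lipid"``, ``"per g DM"`` or
    ``"per 100 g DM"``.  Per g dry matter the chain is
    ``lipid_content x total_fa_content x percent/100``; the other bases
    are linear rescalings.
    """
    pct = profile.percent(fa)
    if profile.total_fa_content is None:
        raise ValueError(f"{profile.matrix_label!r} lacks total_fa_content")
    per_g_lipid = profile.total_fa_content * pct / 100.0
    if basis == "per g lipid":
        return per_g_lipid
    if profile.lipid_content is None:
        raise ValueError(f"{profile.matrix_label!r} lacks lipid_content for basis {basis!r}")
    per_g_dm = profile.lipid_content * per_g_lipid
    if basis == "per g DM":
        return per_g_dm
    if basis == "per 100 g DM":
        return 100.0 * per_g_dm
    raise ValueError(f"unknown basis {basis!r}")


# Ratio definitions: (numerator keys, denominator keys).  Series ratios sum
# the whole omega series; pairwise ratios divide single-acid percents.
_ALA, _LA = "18:3n-3", "18:2n-6"
_EPA, _DHA, _ARA = "20:5n-3", "22:6n-3", "20:4n-6"


def composition_ratios(profile: FAProfile, ndigits: int | None = None) -> dict[str, float | None]:
    """Dietary-quality ratios: n-3:n-6, DHA:EPA, ALA:LA, EPA:ARA.

    A zero denominator yields ``None`` (tables print "-").  With
    ``ndigits`` the values are rounded as printed (1 decimal in the
    trial tables).
    """
    n3 = profile.series_total("n-3")
    n6 = profile.series_total("n-6")
    ratios: dict[str, float | None] = {
        "n3:n6": _safe_div(n3, n6),
        "DHA:EPA": _safe_div(profile.percent(_DHA), profile.percent(_EPA)),
        "ALA:LA": _safe_div(profile.percent(_ALA), profile.percent(_LA)),
        "EPA:ARA": _safe_div(profile.percent(_EPA), profile.percent(_ARA)),
    }
    if ndigits is not None:
        ratios = {k: (None if v is None else round(v, ndigits)) for k, v in ratios.items()}
    return ratios


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def validate_profile(profile: FAProfile) -> list[str]:
    """Data-quality checks; returns a list of warning strings.

    The percent sum over individual acids plus 'Other' classes should be
    near 100; sums in [93, 100.5] pass (published composition tables
    leave a few percent of minor unidentified peaks unreported).
    """
    warnings: list[str] = []
    total = sum(
        v
        for k, v in profile.composition.items()
        if not (is_class_label(k) and k.startswith("Total"))
    )
    if not 93.0 <= total <= 100.5:
        warnings.append(
            f"{profile.matrix_label!r}: percent sum {total:.1f} outside [93, 100.5]"
        )
    return warnings
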