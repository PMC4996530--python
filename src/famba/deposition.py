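"""Diet-versus-tissue deposition-efficiency metrics and absolute tissue
contents.

The percent difference between dietary and tissue concentration of a
fatty acid, ``100 x (diet - tissue)/diet``, reads as a deposition
inefficiency: large positive values mean the acid is depleted in tissue
relative to the feed (oxidised or converted), negative values mean the
tissue is enriched (selective retention or synthesis).  Absolute
contents express tissue composition as mg per 100 g dry matter, the
basis used to compare fillet nutritional value across diets.
"""

from __future__ import annotations

from typing import Iterable

from .fatty_acids import FAProfile, parse_shorthand

__all__ = [
    "diet_tissue_difference",
    "tissue_absolute_content",
    "FA_CLASSES",
]

#: Members of the named fatty-acid classes used in trial tables.  The
#: 'Other ...' entries of a profile are included where the class sums a
#: whole series.
FA_CLASSES: dict[str, tuple[str, ...]] = {
    "n-3 LC-PUFA": ("20:4n-3", "20:5n-3", "22:5n-3", "22:6n-3"),
    "EPA+DHA": ("20:5n-3", "22:6n-3"),
}


def diet_tissue_difference(diet_percent: float, tissue_percent: float) -> float | None:
    """Percent difference of tissue vs diet concentration,
    ``100 x (diet - tissue) / diet``.

    Returns ``None`` when the dietary concentration is zero (the metric
    is undefined; tables print a dash).
    """
    if diet_percent < 0 or tissue_percent < 0:
        raise ValueError("percent concentrations must be >= 0")
    if diet_percent == 0:
        return None
    return 100.0 * (diet_percent - tissue_percent) / diet_percent


def _class_percent(profile: FAProfile, name: str) -> float:
    if name in FA_CLASSES:
        return sum(profile.percent(m) for m in FA_CLASSES[name])
    if name == "total n-3 PUFA":
        return profile.series_total("n-3")
    if name == "total n-6 PUFA":
        return profile.series_total("n-6")
    known = sorted(FA_CLASSES) + ["total n-3 PUFA", "total n-6 PUFA"]
    raise ValueError(f"unknown fatty-acid class {name!r}; known classes: {known}")


def tissue_absolute_content(profile: FAProfile, fa_or_class: str) -> float:
    """Absolute content of an acid or class, mg per 100 g tissue dry matter.

    ``100 x lipid_content x total_fa_content x percent/100``.  Class
    arguments sum their member acids' percents; individual acids and the
    profile's own lumped entries ('Other SFA', ...) are used directly.
    """
    if profile.lipid_content is None or profile.total_fa_content is None:
        raise ValueError(f"{profile.matrix_label!r} lacks lipid/total-FA metadata")
    if fa_or_class in profile.composition:
        pct = profile.percent(fa_or_class)
    else:
        try:
            pct = profile.percent(parse_shorthand(fa_or_class))
        except Exception:
            pct = _class_percent(profile, fa_or_class)
    return 100.0 * profile.lipid_content * profile.total_fa_content * pct / 100.0


def deposition_table(
    diet_profile: FAProfile,
    tissue_profile: FAProfile,
    fatty_acids: Iterable[str],
) -> dict[str, float | None]:
    """Diet-tissue percent differences for several acids or classes."""
    out: dict[str, float | None] = {}
    for name in fatty_acids:
        try:
            d = _class_percent(diet_profile, name)
            t = _class_percent(tissue_profile, name)
        except ValueError:
            d = diet_profile.percent(name)
            t = tissue_profile.percent(name)
        out[name] = diet_tissue_difference(d, t)
    return out
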