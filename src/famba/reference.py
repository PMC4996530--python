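"""Reference data from an 89-day Atlantic salmon smolt feeding trial
comparing three dietary oil sources:

* ``FO``   — 100% fish oil,
* ``FOPO`` — 20% fish oil + 80% poultry oil (commercial-like blend),
* ``TOFX`` — 60% tuna oil + 40% flaxseed oil (high-DHA, high-ALA blend
  emulating oil from transgenic *Camelina*).

The tables hold treatment means: source-oil and feed fatty-acid
compositions (% of total FA) with total-FA content (mg g^-1 lipid),
muscle and liver compositions, tank-mean growth records, the published
whole-body ALA mass-balance partition (umol fish^-1) and the
differentially abundant liver proteins with their raw LFQ group means.
They serve as synthetic-generator defaults and worked-example inputs;
they are not a substitute for tank-level raw data, which is why the
statistical stages are exercised on simulated datasets instead.
"""

from __future__ import annotations

from .fatty_acids import FAProfile
from .trial_metrics import TankRecord

__all__ = [
    "OIL_PROFILES",
    "FEED_PROFILES",
    "MUSCLE_PROFILES",
    "LIVER_PROFILES",
    "GROWTH_TANK_MEANS",
    "GROWTH_PUBLISHED",
    "ALA_MASS_BALANCE_UMOL",
    "DA_PROTEINS",
    "DIETS",
]

DIETS = ("FO", "FOPO", "TOFX")

_FA_ROWS = (
    "14:0", "16:0", "17:0", "18:0", "Other SFA",
    "16:1n-7", "18:1n-7", "18:1n-9", "20:1n-9", "22:1n-11", "Other MUFA",
    "18:2n-6", "18:3n-6", "20:3n-6", "20:4n-6", "Other n-6 PUFA",
    "18:3n-3", "18:4n-3", "20:4n-3", "20:5n-3", "22:5n-3", "22:6n-3",
    "Other n-3 PUFA",
)


def _profile(label, values, total_fa, lipid=None, dm=None):
    return FAProfile(
        matrix_label=label,
        composition=dict(zip(_FA_ROWS, values)),
        total_fa_content=total_fa,
        lipid_content=lipid,
        dry_matter=dm,
    )


# Source oils: fish oil (FO), poultry oil (PO), tuna oil (TO), flaxseed
# oil (FX).  Oils carry no lipid/DM metadata (they are pure lipid).
OIL_PROFILES = {
    "FO": _profile("FO oil", (
        7.5, 17.2, 0.5, 3.4, 1.1,
        9.4, 3.2, 8.4, 0.8, 0.4, 1.4,
        1.4, 0.3, 0.2, 0.8, 0.7,
        0.9, 3.2, 0.8, 16.0, 1.8, 13.5, 0.7), 867.0),
    "PO": _profile("PO oil", (
        1.4, 21.3, 0.2, 5.9, 0.4,
        6.1, 2.6, 41.4, 0.5, 0.0, 0.8,
        11.6, 0.1, 0.1, 0.3, 0.2,
        1.9, 0.3, 0.1, 1.5, 0.2, 1.3, 0.1), 838.4),
    "TO": _profile("TO oil", (
        3.0, 20.7, 1.3, 5.9, 2.3,
        4.6, 2.3, 12.6, 1.2, 0.3, 1.5,
        1.2, 0.1, 0.1, 1.8, 2.0,
        0.5, 0.6, 0.4, 5.3, 1.2, 27.0, 0.3), 777.4),
    "FX": _profile("FX oil", (
        0.0, 5.1, 0.1, 3.7, 0.5,
        0.1, 1.0, 20.2, 0.3, 0.0, 0.1,
        11.7, 0.0, 0.0, 0.0, 0.1,
        56.4, 0.0, 0.0, 0.1, 0.0, 0.0, 0.0), 975.4),
}

# Feeds: lipid content g g^-1 DM from the proximate table; dry matter
# g g^-1 as-fed.
FEED_PROFILES = {
    "FO": _profile("FO feed", (
        6.6, 17.5, 0.5, 3.6, 1.1,
        8.9, 3.2, 8.8, 0.8, 0.4, 1.5,
        2.7, 0.3, 0.2, 0.6, 0.7,
        1.1, 2.9, 0.8, 15.6, 1.9, 13.5, 0.7), 852.5, lipid=0.2379, dm=0.9065),
    "FOPO": _profile("FOPO feed", (
        2.8, 20.1, 0.3, 5.2, 0.6,
        6.7, 2.9, 31.0, 0.6, 0.2, 1.1,
        9.5, 0.2, 0.1, 0.5, 0.4,
        1.7, 1.0, 0.3, 5.5, 0.8, 5.4, 0.2), 934.7, lipid=0.2479, dm=0.8972),
    "TOFX": _profile("TOFX feed", (
        2.1, 15.3, 0.8, 5.1, 1.5,
        3.3, 2.0, 15.4, 0.8, 0.2, 1.1,
        7.5, 0.1, 0.1, 1.1, 1.3,
        18.8, 0.6, 0.3, 4.4, 0.9, 14.7, 0.2), 865.6, lipid=0.2425, dm=0.9020),
}

# White dorsal muscle; lipid and DM are the cross-treatment means
# (per-treatment proximate values were not published).
_MUSCLE_LIPID, _MUSCLE_DM = 0.0985, 0.2569
MUSCLE_PROFILES = {
    "Initial": _profile("initial muscle", (
        2.7, 15.8, 0.3, 5.0, 0.6,
        6.0, 3.3, 29.3, 1.5, 0.4, 1.3,
        8.1, 0.2, 0.4, 0.8, 0.9,
        1.1, 1.0, 0.5, 3.5, 1.5, 12.1, 0.7), 871.0, _MUSCLE_LIPID, _MUSCLE_DM),
    "FO": _profile("FO muscle", (
        4.0, 17.7, 0.4, 4.7, 0.7,
        6.5, 3.5, 13.0, 0.8, 0.3, 1.5,
        2.9, 0.1, 0.3, 1.0, 0.8,
        1.0, 1.9, 0.8, 9.0, 3.3, 20.8, 1.0), 858.8, _MUSCLE_LIPID, _MUSCLE_DM),
    "FOPO": _profile("FOPO muscle", (
        2.0, 18.4, 0.3, 5.1, 0.5,
        5.3, 3.3, 28.7, 1.3, 0.1, 1.3,
        7.5, 0.2, 0.5, 0.9, 0.9,
        1.3, 0.9, 0.4, 3.8, 1.4, 13.0, 0.6), 895.8, _MUSCLE_LIPID, _MUSCLE_DM),
    "TOFX": _profile("TOFX muscle", (
        1.5, 15.2, 0.6, 5.3, 0.9,
        2.9, 2.3, 16.9, 1.0, 0.2, 1.2,
        6.4, 0.1, 0.2, 1.1, 1.8,
        12.8, 1.0, 0.6, 3.2, 1.4, 19.9, 0.6), 882.7, _MUSCLE_LIPID, _MUSCLE_DM),
}

_LIVER_LIPID, _LIVER_DM = 0.1534, 0.2589
LIVER_PROFILES = {
    "Initial": _profile("initial liver", (
        1.0, 18.1, 0.3, 5.8, 0.4,
        3.8, 3.5, 23.7, 0.7, 0.2, 2.1,
        6.5, 0.3, 0.5, 2.1, 0.8,
        0.9, 0.9, 0.4, 4.7, 1.6, 19.6, 0.3), 698.9, _LIVER_LIPID, _LIVER_DM),
    "FO": _profile("FO liver", (
        1.9, 15.9, 0.4, 6.8, 0.5,
        2.9, 3.5, 12.1, 1.4, 0.1, 3.2,
        1.4, 0.0, 0.4, 3.4, 0.9,
        0.3, 0.5, 0.6, 10.3, 3.2, 27.4, 0.4), 673.7, _LIVER_LIPID, _LIVER_DM),
    "FOPO": _profile("FOPO liver", (
        1.0, 14.7, 0.2, 6.5, 0.8,
        2.6, 3.2, 22.4, 2.2, 0.0, 2.8,
        4.2, 0.1, 1.2, 3.4, 1.4,
        0.4, 0.3, 0.3, 5.7, 1.5, 23.1, 0.3), 676.0, _LIVER_LIPID, _LIVER_DM),
    "TOFX": _profile("TOFX liver", (
        0.9, 14.8, 0.7, 7.3, 0.7,
        1.7, 2.4, 15.2, 1.3, 0.1, 2.5,
        3.9, 0.1, 0.4, 4.0, 2.0,
        6.0, 0.5, 0.7, 4.8, 1.4, 25.1, 0.3), 678.9, _LIVER_LIPID, _LIVER_DM),
}

# Tank-mean growth inputs (g fish^-1) over the 89-day trial.
GROWTH_TANK_MEANS = {
    "FO": TankRecord("FO-mean", "FO", wi_g=104.7, wf_g=222.8, fi_g=130.2, days=89),
    "FOPO": TankRecord("FOPO-mean", "FOPO", wi_g=105.4, wf_g=229.3, fi_g=137.3, days=89),
    "TOFX": TankRecord("TOFX-mean", "TOFX", wi_g=107.0, wf_g=214.1, fi_g=131.4, days=89),
}

# Published treatment means of the derived indices (for cross-checks and
# generator targets).
GROWTH_PUBLISHED = {
    "FO": {"sgr": 0.85, "fer": 0.91, "k": 1.1, "hsi": 1.4, "gsi": 10.4, "pcsi": 4.9},
    "FOPO": {"sgr": 0.87, "fer": 0.90, "k": 1.1, "hsi": 1.2, "gsi": 9.3, "pcsi": 4.4},
    "TOFX": {"sgr": 0.78, "fer": 0.81, "k": 1.0, "hsi": 1.3, "gsi": 8.5, "pcsi": 4.1},
}

# Whole-body ALA mass-balance treatment means, umol fish^-1.
ALA_MASS_BALANCE_UMOL = {
    "FO": {"net_intake": 891.4, "accumulated": 818.4, "disappeared": 73.1,
           "oxidized": 0.0, "bioconverted": 73.1},
    "FOPO": {"net_intake": 1677.0, "accumulated": 1271.0, "disappeared": 406.0,
             "oxidized": 401.5, "bioconverted": 4.5},
    "TOFX": {"net_intake": 15742.2, "accumulated": 9228.0, "disappeared": 6514.2,
             "oxidized": 6401.6, "bioconverted": 112.6},
}

# Differentially abundant liver proteins (TOFX vs FO): raw LFQ group
# means over n=4 tank pools, published signed fold change, unique
# peptide counts.  None marks not-detected in that group.
DA_PROTEINS = [
    # (accession, gene, lfq_fo, lfq_tofx, fold_change, unique_peptides)
    ("B5XCS5", "ATP5J", 1.21e6, 9.19e5, -1.3, 2),
    ("B5X2T3", "ALDH2", 7.53e7, 5.40e7, -1.4, 25),
    ("C0HBJ4", "RAB1A", 1.28e6, 1.80e6, 1.4, 3),
    ("B5X462", "GSTT1", 4.55e6, 6.63e6, 1.5, 9),
    ("Q68S98", "", 7.19e6, 1.09e7, 1.5, 2),
    ("B5X313", "PAHX", 5.37e6, 8.39e6, 1.6, 11),
    ("B5DG71", "H33", 4.69e7, 7.14e7, 1.5, 2),
    ("B5X180", "UD2A2", 1.23e6, 2.43e6, 2.0, 5),
    ("B5X1I8", "STT3A", 7.64e5, 1.76e6, 2.3, 5),
    ("B5X322", "S61A1", 1.01e6, 2.78e6, 2.8, 4),
    ("B5X2R4", "CP2M1", 1.35e6, 5.59e6, 4.3, 12),
    ("B5X970", "PNPO", 2.25e6, None, None, 4),
    ("B5DGE7", "rtn4", None, 8.42e5, None, 3),
    ("C0H9Z9", "F13A", None, 1.15e6, None, 3),
]
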