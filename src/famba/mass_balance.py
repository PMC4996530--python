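"""Whole-body fatty-acid mass balance (FAMB).

The balance partitions each fatty acid's digestible (net) intake over a
trial into three fates: accumulation in the body pool, disappearance
through beta-oxidation, and bioconversion to downstream products of a
desaturation/elongation pathway.  All accounting is in moles
(micromoles per fish), because each desaturation or elongation step
transforms one molecule of precursor into one molecule of product.

The pathway is a linear chain; for the omega-3 series::

    18:3n-3 (ALA) -d6-> 18:4n-3 (SDA) -elong-> 20:4n-3 (ETA)
      -d5-> 20:5n-3 (EPA) -elong-> 22:5n-3 (DPA) -> 22:6n-3 (DHA)

The DPA->DHA step is modelled as a single step (the C24 intermediates
of the Sprecher shunt are not separate pools, as no C24 acids are
quantified in the composition tables).

Attribution is backward from the terminal product: any appearance of a
node in excess of its own net intake must have been synthesised from
its immediate precursor, and that demand propagates up the chain.  A
node's disappearance not explained by onward conversion is attributed
to beta-oxidation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .fatty_acids import FAProfile, FattyAcid, parse_shorthand, molar_mass

__all__ = [
    "Pathway",
    "N3_PATHWAY",
    "MassBalanceInput",
    "MassBalanceResult",
    "fa_moles",
    "net_intake",
    "partition_chain",
    "mass_balance",
    "apparent_enzyme_flux",
    "MassBalanceError",
]


class MassBalanceError(ValueError):
    """Inconsistent inputs to the balance (e.g. the chain-head fatty acid
    appears in the body in excess of its net intake: it cannot be
    synthesised, so the inputs contradict each other)."""


@dataclass(frozen=True)
class Pathway:
    """A linear biosynthetic chain of (precursor, product, enzyme) steps."""

    steps: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        nodes = self.nodes
        if len(set(nodes)) != len(nodes):
            raise ValueError("pathway must be a linear chain without repeats")
        prev_series: str | None = None
        prev_carbons = 0
        for shorthand in nodes:
            fa = parse_shorthand(shorthand)
            if fa.carbons < prev_carbons:
                raise ValueError("product carbons must not decrease along the chain")
            if prev_series is not None and fa.omega_series != prev_series:
                raise ValueError("all pathway members must share one omega series")
            prev_series, prev_carbons = fa.omega_series, fa.carbons

    @property
    def nodes(self) -> tuple[str, ...]:
        """Fatty acids in chain order, head (dietary precursor) first."""
        out = [self.steps[0][0]]
        for prec, prod, _ in self.steps:
            if prec != out[-1]:
                raise ValueError("steps are not chained head-to-tail")
            out.append(prod)
        return tuple(out)

    @property
    def head(self) -> str:
        return self.steps[0][0]

    @property
    def terminal(self) -> str:
        return self.steps[-1][1]


#: The omega-3 biosynthetic chain from ALA to DHA.
N3_PATHWAY = Pathway(
    steps=(
        ("18:3n-3", "18:4n-3", "delta-6 desaturase"),
        ("18:4n-3", "20:4n-3", "elongase"),
        ("20:4n-3", "20:5n-3", "delta-5 desaturase"),
        ("20:5n-3", "22:5n-3", "elongase"),
        ("22:5n-3", "22:6n-3", "elongase + delta-6 desaturase + beta-oxidation"),
    )
)


def fa_moles(
    profile: FAProfile, mass_g: float, apply_dry_matter: bool = True
) -> dict[str, float]:
    """Micromoles of each individual fatty acid in ``mass_g`` of material.

    ``mass_g`` is on an as-is (wet / as-fed) basis when
    ``apply_dry_matter`` is true, otherwise already dry matter.  The
    chain is mass x [DM] x lipid x total-FA x percent/100 / molar mass,
    scaled to micromoles.  Lumped class entries carry no molecular
    identity and are skipped.
    """
    if profile.total_fa_content is None or profile.lipid_content is None:
        raise ValueError(f"{profile.matrix_label!r} lacks lipid/total-FA metadata")
    dm = 1.0
    if apply_dry_matter:
        if profile.dry_matter is None:
            raise ValueError(f"{profile.matrix_label!r} lacks dry-matter content")
        dm = profile.dry_matter
    lipid_g = mass_g * dm * profile.lipid_content
    out: dict[str, float] = {}
    for fa in profile.individual_acids():
        mg = lipid_g * profile.total_fa_content * profile.percent(fa) / 100.0
        out[fa.shorthand] = mg / molar_mass(fa) * 1000.0  # mg / (g mol^-1) = mmol
    return out


def net_intake(gross_umol: float, ad_percent: float) -> float:
    """Digestible intake (micromol) = gross intake x AD/100."""
    if not 0.0 <= ad_percent <= 100.0:
        raise ValueError(f"apparent digestibility must lie in [0, 100], got {ad_percent}")
    return gross_umol * ad_percent / 100.0


@dataclass
class MassBalanceInput:
    """Everything needed to run the balance for one tank.

    ``ad`` maps fatty-acid shorthand to apparent digestibility (%);
    acids without an entry use ``default_ad``.  Body states are (mean
    fish weight g, carcass profile); the initial state typically uses a
    pooled initial-population carcass composition.
    """

    feed: FAProfile
    fi_g: float
    ad: Mapping[str, float]
    initial_weight_g: float
    initial_profile: FAProfile
    final_weight_g: float
    final_profile: FAProfile
    days: int
    default_ad: float = 100.0


@dataclass
class MassBalanceResult:
    """Per-fatty-acid partition of net intake, all in micromol fish^-1.

    ``components`` has one row per pathway node with columns
    gross_intake, net_intake, flux_in, accumulated, disappeared,
    oxidized, bioconverted, plus percent-of-net-intake twins.
    ``step_flux_umol`` maps (precursor, product) to the apparent
    conversion flux through that step.  ``clamping_events`` records
    every non-negativity clamp with its magnitude.
    """

    pathway: Pathway
    components: pd.DataFrame
    step_flux_umol: dict[tuple[str, str], float]
    clamping_events: list[tuple[str, str, float]] = field(default_factory=list)

    def percent_of_net_intake(self, fa: str, component: str) -> float | None:
        net = self.components.loc[fa, "net_intake"]
        if net <= 0:
            return None
        return 100.0 * self.components.loc[fa, component] / net


_CLOSURE_RTOL = 1e-9


def partition_chain(
    net: Mapping[str, float],
    appearance: Mapping[str, float],
    pathway: Pathway = N3_PATHWAY,
    gross: Mapping[str, float] | None = None,
) -> MassBalanceResult:
    """Partition net intakes given observed body-pool appearances.

    ``net`` and ``appearance`` map pathway shorthands to micromoles
    (appearance = final pool - initial pool; may be negative).  Missing
    nodes count as zero.  Backward attribution: the conversion flux
    into each node is the excess of its appearance plus onward flux over
    its net intake, clamped at zero; that flux is demanded from the
    immediate precursor.
    """
    nodes = pathway.nodes
    n = {k: float(net.get(k, 0.0)) for k in nodes}
    a = {k: float(appearance.get(k, 0.0)) for k in nodes}
    for k, v in n.items():
        if v < 0:
            raise MassBalanceError(f"negative net intake for {k}: {v}")

    # Backward pass: conversion flux required from each node's precursor.
    flux_in: dict[str, float] = {k: 0.0 for k in nodes}
    flux_out: dict[str, float] = {k: 0.0 for k in nodes}
    for node in reversed(nodes[1:]):
        demand = a[node] + flux_out[node] - n[node]
        flux_in[node] = max(0.0, demand)
        prec = nodes[nodes.index(node) - 1]
        flux_out[prec] = flux_in[node]

    head = pathway.head
    if a[head] - n[head] > _CLOSURE_RTOL * max(1.0, n[head]):
        raise MassBalanceError(
            f"{head} accumulated in the body ({a[head]:.3f} umol) in excess "
            f"of its net intake ({n[head]:.3f} umol); it cannot be "
            "synthesised, so the inputs are inconsistent"
        )

    clamps: list[tuple[str, str, float]] = []
    rows = []
    for node in nodes:
        supply = n[node] + flux_in[node]
        # negatives below this are floating-point noise, not data issues
        eps = _CLOSURE_RTOL * max(1.0, supply)
        # disappearance uses the raw (possibly negative) appearance so a
        # shrinking pool folds into that node's own oxidation; the
        # accumulated component is then floored at zero with a log entry
        disappeared = supply - a[node]
        accumulated = a[node]
        if accumulated < 0:
            if accumulated < -eps:
                clamps.append((node, "accumulated", -accumulated))
            accumulated = 0.0
        if disappeared < 0:
            if disappeared < -eps:
                clamps.append((node, "disappeared", -disappeared))
            disappeared = 0.0
        bioconverted = flux_out[node]
        oxidized = disappeared - bioconverted
        if oxidized < 0:
            if oxidized < -eps:
                clamps.append((node, "oxidized", -oxidized))
            oxidized = 0.0
        rows.append(
            {
                "fatty_acid": node,
                "gross_intake": float(gross.get(node, math.nan)) if gross else math.nan,
                "net_intake": n[node],
                "flux_in": flux_in[node],
                "appearance": a[node],
                "accumulated": accumulated,
                "disappeared": disappeared,
                "oxidized": oxidized,
                "bioconverted": bioconverted,
            }
        )
    frame = pd.DataFrame(rows).set_index("fatty_acid")
    for comp in ("accumulated", "disappeared", "oxidized", "bioconverted"):
        frame[f"{comp}_pct"] = [
            100.0 * frame.loc[k, comp] / frame.loc[k, "net_intake"]
            if frame.loc[k, "net_intake"] > 0
            else math.nan
            for k in frame.index
        ]
    step_flux = {
        (prec, prod): flux_in[prod] for prec, prod, _ in pathway.steps
    }
    return MassBalanceResult(pathway, frame, step_flux, clamps)


def mass_balance(
    inp: MassBalanceInput, pathway: Pathway = N3_PATHWAY
) -> MassBalanceResult:
    """Run the full balance for one tank from feed, intake, digestibility
    and initial/final carcass composition."""
    gross = fa_moles(inp.feed, inp.fi_g, apply_dry_matter=True)
    nets = {
        k: net_intake(v, float(inp.ad.get(k, inp.default_ad)))
        for k, v in gross.items()
    }
    pool_i = fa_moles(inp.initial_profile, inp.initial_weight_g, apply_dry_matter=True)
    pool_f = fa_moles(inp.final_profile, inp.final_weight_g, apply_dry_matter=True)
    appearance = {
        k: pool_f.get(k, 0.0) - pool_i.get(k, 0.0)
        for k in set(pool_i) | set(pool_f) | set(nets)
    }
    return partition_chain(nets, appearance, pathway, gross=gross)


def apparent_enzyme_flux(
    result: MassBalanceResult, initial_weight_g: float, final_weight_g: float, days: int
) -> dict[tuple[str, str], float]:
    """Per-step apparent conversion rates in nmol g^-1 day^-1.

    Normalises each step's micromole flux by the trial duration and the
    arithmetic mean body weight (Wi+Wf)/2.
    """
    if days <= 0:
        raise ValueError("days must be positive")
    mean_w = (initial_weight_g + final_weight_g) / 2.0
    if mean_w <= 0:
        raise ValueError("mean body weight must be positive")
    return {
        step: flux * 1000.0 / (mean_w * days)
        for step, flux in result.step_flux_umol.items()
    }


def treatment_summary(
    tank_results: Mapping[str, MassBalanceResult],
    fa: str,
    mode: str = "mean_of_ratios",
) -> pd.DataFrame:
    """Mean +/- SEM of the partition components for one fatty acid over
    replicate tanks.

    ``mode="mean_of_ratios"`` averages per-tank percentages (how trial
    tables are built, which is why printed '%' rows differ slightly from
    ratios of printed means); ``"ratio_of_means"`` recomputes
    percentages from the averaged micromole components.
    """
    comps = ("net_intake", "accumulated", "disappeared", "oxidized", "bioconverted")
    per_tank = pd.DataFrame(
        {t: r.components.loc[fa, list(comps)] for t, r in tank_results.items()}
    ).T
    k = len(per_tank)
    out = pd.DataFrame({"mean": per_tank.mean(), "sem": per_tank.std(ddof=1) / math.sqrt(k) if k > 1 else math.nan})
    if mode == "mean_of_ratios":
        pct = pd.DataFrame(
            {
                t: {
                    c: (p if (p := r.percent_of_net_intake(fa, c)) is not None else math.nan)
                    for c in comps[1:]
                }
                for t, r in tank_results.items()
            }
        ).T
        for c in comps[1:]:
            out.loc[f"{c}_pct", "mean"] = pct[c].mean()
            out.loc[f"{c}_pct", "sem"] = pct[c].std(ddof=1) / math.sqrt(k) if k > 1 else math.nan
    elif mode == "ratio_of_means":
        net_mean = out.loc["net_intake", "mean"]
        for c in comps[1:]:
            out.loc[f"{c}_pct", "mean"] = 100.0 * out.loc[c, "mean"] / net_mean
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out
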