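"""Seeded generators for feeding-trial and proteomics datasets with
known ground truth.

Every generator is a pure function of (config, seed): the same inputs
reproduce the same dataset byte for byte.  Defaults mirror the study
conditions of the oil-blend trial in :mod:`famba.reference` — three
diets, four tanks per diet split over two recirculation systems, 89
days, feed compositions from the reference tables — so synthetic
outputs land in realistic ranges.

``forward_flux`` is the generative inverse of the mass-balance engine:
it pushes known net intakes through a pathway with prescribed fate
fractions and returns the body-pool appearances the balance would
observe.  The backward balance recovers the prescribed partition
exactly whenever downstream nodes do not beta-oxidize (their
disappearance is then fully explained by onward conversion); the
defaults sample that identifiable regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .fatty_acids import FAProfile, molar_mass, parse_shorthand
from .mass_balance import N3_PATHWAY, Pathway, fa_moles
from .proteome import ProteinGroupTable
from .trial_metrics import TankRecord

__all__ = [
    "TrialConfig",
    "TrialDataset",
    "simulate_trial",
    "forward_flux",
    "simulate_proteome",
]

# Default per-class apparent digestibility (%) used when a fatty acid has
# no explicit entry: saturates are absorbed worst, PUFA best, matching
# the ordering seen in marker studies (overall lipid AD ~94%).
_CLASS_AD = {"SFA": 85.0, "MUFA": 92.0, "PUFA": 96.0}

# Default ALA fate fractions (accumulated, oxidized, bioconverted) per
# diet, derived from the reference mass-balance partition; renormalised
# because the published rounded components can overshoot the net intake
# by a trifle.
def _fates(v: dict) -> tuple[float, float, float]:
    f = (v["accumulated"], v["oxidized"], v["bioconverted"])
    scale = max(v["net_intake"], sum(f))
    return tuple(x / scale for x in f)


_DEFAULT_ALA_FATES = {
    diet: _fates(v) for diet, v in reference.ALA_MASS_BALANCE_UMOL.items()
}


def _default_fa_ad(profile: FAProfile) -> dict[str, float]:
    out = {}
    for fa in profile.individual_acids():
        if fa.double_bonds == 0:
            out[fa.shorthand] = _CLASS_AD["SFA"]
        elif fa.double_bonds == 1:
            out[fa.shorthand] = _CLASS_AD["MUFA"]
        else:
            out[fa.shorthand] = _CLASS_AD["PUFA"]
    return out


@dataclass
class TrialConfig:
    """Study-design and ground-truth parameters for a simulated trial.

    Noise terms: ``tank_cv`` is the lognormal coefficient of variation
    on tank weights, ``faeces_cv`` on faecal concentrations, and
    ``system_effect`` a multiplicative offset on growth rate between
    the two recirculation systems.  With all three at zero the derived
    metrics recover the configured targets exactly.
    """

    diets: tuple[str, ...] = reference.DIETS
    n_tanks_per_diet: int = 4
    n_systems: int = 2
    days: int = 89
    initial_weight_g: float = 105.7
    sgr_targets: Mapping[str, float] = field(
        default_factory=lambda: {d: reference.GROWTH_PUBLISHED[d]["sgr"] for d in reference.DIETS}
    )
    fer_targets: Mapping[str, float] = field(
        default_factory=lambda: {d: reference.GROWTH_PUBLISHED[d]["fer"] for d in reference.DIETS}
    )
    feed_profiles: Mapping[str, FAProfile] = field(
        default_factory=lambda: dict(reference.FEED_PROFILES)
    )
    tank_cv: float = 0.03
    system_effect: float = 0.02
    faeces_cv: float = 0.01
    ad_dry_matter: float = 69.4
    marker_diet_conc: float = 0.1  # % yttrium oxide in the diet
    nutrient_diet_conc: Mapping[str, float] = field(
        default_factory=lambda: {"lipid": 24.0, "protein": 49.0}
    )
    nutrient_ad: Mapping[str, float] = field(
        default_factory=lambda: {"lipid": 94.0, "protein": 89.3}
    )
    fa_ad: Mapping[str, float] | None = None  # per-FA AD %; None -> per-class defaults
    ala_fates: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_ALA_FATES)
    )
    downstream_retention: float = 0.9  # accumulate fraction at intermediate nodes
    non_pathway_retention: float = 0.6
    carcass_lipid: float = 0.4143
    carcass_dm: float = 0.3431
    carcass_total_fa: float = 900.0

    def __post_init__(self) -> None:
        if self.tank_cv < 0 or self.faeces_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        for name, m in (("nutrient_ad", self.nutrient_ad), ("fa_ad", self.fa_ad or {})):
            for k, v in m.items():
                if not 0 <= v <= 100:
                    raise ValueError(f"{name}[{k!r}] = {v} outside [0, 100]")
        for d, (a, o, c) in self.ala_fates.items():
            if min(a, o, c) < 0 or a + o + c > 1 + 1e-9:
                raise ValueError(f"fate fractions for {d!r} must be >= 0 and sum <= 1")


@dataclass
class TrialDataset:
    """A simulated trial: tank records, carcass profiles and the ground
    truth used to generate them."""

    config: TrialConfig
    tanks: list[TankRecord]
    initial_carcass: FAProfile
    final_carcass: dict[str, FAProfile]  # tank_id -> profile
    fa_ad: dict[str, dict[str, float]]  # diet -> fatty acid -> AD %
    ground_truth: dict


def forward_flux(
    net_intake: Mapping[str, float],
    fractions: Mapping[str, tuple[float, float, float]],
    pathway: Pathway = N3_PATHWAY,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Push net intakes through the pathway with prescribed fate fractions.

    ``fractions`` maps fatty acid to (accumulate, oxidize, convert
    onward); nodes without an entry retain everything.  Any fraction
    shortfall from 1 counts as additional oxidation (mass must go
    somewhere).  Returns the body-pool appearance per node and a truth
    table of the micromole amounts; total moles are conserved.
    """
    appearance: dict[str, float] = {}
    rows = []
    inflow = 0.0
    for node in pathway.nodes:
        acc, ox, conv = fractions.get(node, (1.0, 0.0, 0.0))
        if min(acc, ox, conv) < 0:
            raise ValueError(f"negative fate fraction for {node}")
        if acc + ox + conv > 1 + 1e-12:
            raise ValueError(f"fate fractions for {node} sum above 1")
        if node == pathway.terminal and conv > 0:
            raise ValueError("the terminal product cannot convert onward")
        ox_total = ox + max(0.0, 1.0 - acc - ox - conv)
        supply = float(net_intake.get(node, 0.0)) + inflow
        appearance[node] = acc * supply
        rows.append(
            {
                "fatty_acid": node,
                "supply": supply,
                "accumulated": acc * supply,
                "oxidized": ox_total * supply,
                "bioconverted": conv * supply,
            }
        )
        inflow = conv * supply
    return appearance, pd.DataFrame(rows).set_index("fatty_acid")


def _pools_to_profile(
    label: str,
    pools_umol: Mapping[str, float],
    mass_g: float,
    cfg: TrialConfig,
) -> FAProfile:
    """Express body pools (umol per fish) as a carcass composition.

    The percent of each acid follows from its mass against the carcass
    fatty-acid capacity (mass x DM x lipid x total-FA); an 'Other SFA'
    filler entry tops the composition up toward 100%.
    """
    capacity_mg = mass_g * cfg.carcass_dm * cfg.carcass_lipid * cfg.carcass_total_fa
    comp: dict[str, float] = {}
    for shorthand, umol in pools_umol.items():
        mg = umol * molar_mass(parse_shorthand(shorthand)) / 1000.0
        comp[shorthand] = 100.0 * mg / capacity_mg
    total = sum(comp.values())
    comp["Other SFA"] = max(0.0, 100.0 - total)
    return FAProfile(
        matrix_label=label,
        composition=comp,
        total_fa_content=cfg.carcass_total_fa,
        lipid_content=cfg.carcass_lipid,
        dry_matter=cfg.carcass_dm,
    )


def simulate_trial(config: TrialConfig | None = None, seed: int = 0) -> TrialDataset:
    """Simulate one feeding trial with known growth, digestibility and
    fatty-acid-flux ground truth.

    Tank weights follow exponential growth at the configured specific
    growth rate with lognormal tank noise; feed intake realises the
    configured feed efficiency; faecal marker and nutrient
    concentrations are consistent with the configured apparent
    digestibilities; final carcass compositions realise the configured
    fatty-acid fate fractions through :func:`forward_flux`.  The initial
    carcass composition is a synthetic stand-in built from the reference
    initial-muscle fatty-acid profile with carcass-level lipid and
    dry-matter contents.
    """
    cfg = config or TrialConfig()
    rng = np.random.default_rng(seed)

    init_muscle = reference.MUSCLE_PROFILES["Initial"]
    initial_carcass = FAProfile(
        matrix_label="initial carcass (synthetic)",
        composition=dict(init_muscle.composition),
        total_fa_content=cfg.carcass_total_fa,
        lipid_content=cfg.carcass_lipid,
        dry_matter=cfg.carcass_dm,
    )

    fa_ad: dict[str, dict[str, float]] = {}
    tanks: list[TankRecord] = []
    final_carcass: dict[str, FAProfile] = {}
    truth: dict = {"tanks": {}, "config": cfg}
    conc_factor = 1.0 / (1.0 - cfg.ad_dry_matter / 100.0)

    for diet in cfg.diets:
        feed = cfg.feed_profiles[diet]
        ad_map = dict(cfg.fa_ad) if cfg.fa_ad is not None else _default_fa_ad(feed)
        fa_ad[diet] = ad_map
        r = cfg.sgr_targets[diet] / 100.0
        for t in range(cfg.n_tanks_per_diet):
            system = f"S{t % cfg.n_systems + 1}"
            tank_id = f"{diet}-{t + 1}"
            sys_mult = 1.0 + cfg.system_effect * (1 if system == "S1" else -1)
            wi = cfg.initial_weight_g * math.exp(rng.normal(0.0, cfg.tank_cv))
            wf = wi * math.exp(r * sys_mult * cfg.days) * math.exp(
                rng.normal(0.0, cfg.tank_cv)
            )
            fi = (wf - wi) / cfg.fer_targets[diet]

            marker: dict[str, tuple[float, float]] = {
                "yttrium": (
                    cfg.marker_diet_conc,
                    cfg.marker_diet_conc
                    * conc_factor
                    * math.exp(rng.normal(0.0, cfg.faeces_cv)),
                )
            }
            for analyte, x_diet in cfg.nutrient_diet_conc.items():
                ad = cfg.nutrient_ad.get(analyte, 90.0)
                x_faeces = (
                    x_diet
                    * (1.0 - ad / 100.0)
                    * conc_factor
                    * math.exp(rng.normal(0.0, cfg.faeces_cv))
                )
                marker[analyte] = (x_diet, x_faeces)

            rec = TankRecord(
                tank_id=tank_id,
                diet=diet,
                system_id=system,
                n_fish=26,
                wi_g=wi,
                wf_g=wf,
                fi_g=fi,
                days=cfg.days,
                marker=marker,
            )
            tanks.append(rec)

            gross = fa_moles(feed, fi, apply_dry_matter=True)
            nets = {k: v * ad_map.get(k, 95.0) / 100.0 for k, v in gross.items()}
            fractions = {N3_PATHWAY.head: cfg.ala_fates[diet]}
            for node in N3_PATHWAY.nodes[1:-1]:
                fractions[node] = (
                    cfg.downstream_retention,
                    0.0,
                    1.0 - cfg.downstream_retention,
                )
            fractions[N3_PATHWAY.terminal] = (1.0, 0.0, 0.0)
            pathway_net = {k: nets.get(k, 0.0) for k in N3_PATHWAY.nodes}
            appearance, flux_truth = forward_flux(pathway_net, fractions)

            pool_i = fa_moles(initial_carcass, wi, apply_dry_matter=True)
            pools_f: dict[str, float] = {}
            for k, net_k in nets.items():
                if k in appearance:
                    pools_f[k] = pool_i.get(k, 0.0) + appearance[k]
                else:
                    pools_f[k] = pool_i.get(k, 0.0) + cfg.non_pathway_retention * net_k
            final_carcass[tank_id] = _pools_to_profile(
                f"{tank_id} final carcass", pools_f, wf, cfg
            )
            truth["tanks"][tank_id] = {
                "diet": diet,
                "system": system,
                "sgr": 100.0 * math.log(wf / wi) / cfg.days,
                "fer": cfg.fer_targets[diet],
                "net_intake_umol": pathway_net,
                "flux": flux_truth,
                "fa_ad": ad_map,
            }
    truth["sgr_targets"] = dict(cfg.sgr_targets)
    truth["fer_targets"] = dict(cfg.fer_targets)
    truth["nutrient_ad"] = dict(cfg.nutrient_ad)
    return TrialDataset(cfg, tanks, initial_carcass, final_carcass, fa_ad, truth)


def simulate_proteome(
    n_proteins: int = 1000,
    samples_per_group: int = 4,
    diets: Sequence[str] = reference.DIETS,
    spikes: Sequence[tuple[int, str, float]] = (),
    seed: int = 0,
    sample_shifts: Sequence[float] | None = None,
    variance_factors: Mapping[str, float] | None = None,
    residual_sd: float = 0.3,
    prior_df: float = 4.0,
    baseline_mean: float = 21.0,
    baseline_sd: float = 2.0,
    missingness: bool = True,
    detection_midpoint: float = 16.0,
    detection_scale: float = 1.0,
    n_single_peptide: int = 0,
) -> tuple[ProteinGroupTable, dict]:
    """Simulate an LFQ protein-group table with known ground truth.

    Log2 intensities are ``baseline + sample shift + spike effect +
    noise``: baselines are normal across proteins (lognormal raw
    intensities), per-protein residual variances follow a scaled
    inverse-chi-square with ``prior_df`` and scale ``residual_sd**2``
    (matching the moderated-t model), ``spikes`` are (protein index,
    diet, log2 effect) triples, ``sample_shifts`` exercise
    normalization, and ``variance_factors`` (sample name -> factor)
    inflate individual samples' noise to exercise quality weights.
    Detection is intensity-dependent: the probability of observing a
    value follows a logistic curve in log2 intensity, so low-abundance
    proteins go missing more often; zeros encode not-detected.
    """
    rng = np.random.default_rng(seed)
    sample_names = []
    meta_rows = []
    for d in diets:
        for i in range(samples_per_group):
            sample_names.append(f"{d}_{i + 1}")
            meta_rows.append({"diet": d, "system": f"S{i % 2 + 1}", "tank": f"{d}-{i + 1}"})
    samples = pd.DataFrame(meta_rows, index=sample_names)
    n_samp = len(sample_names)

    shifts = np.zeros(n_samp) if sample_shifts is None else np.asarray(sample_shifts, float)
    if len(shifts) != n_samp:
        raise ValueError("sample_shifts length must match the number of samples")
    vfac = np.ones(n_samp)
    if variance_factors:
        for name, f in variance_factors.items():
            if f <= 0:
                raise ValueError("variance factors must be positive")
            vfac[sample_names.index(name)] = f

    mu = rng.normal(baseline_mean, baseline_sd, size=n_proteins)
    # scaled inverse-chi-square residual variances
    sd_g = residual_sd * np.sqrt(prior_df / rng.chisquare(prior_df, size=n_proteins))
    effects = np.zeros((n_proteins, n_samp))
    for idx, diet, eff in spikes:
        effects[idx, samples["diet"].to_numpy() == diet] += eff

    y = (
        mu[:, None]
        + shifts[None, :]
        + effects
        + rng.standard_normal((n_proteins, n_samp)) * sd_g[:, None] * np.sqrt(vfac)[None, :]
    )
    intens = np.power(2.0, y)
    if missingness:
        p_detect = 1.0 / (1.0 + np.exp(-(y - detection_midpoint) / detection_scale))
        detected = rng.random((n_proteins, n_samp)) < p_detect
        intens = np.where(detected, intens, 0.0)

    peptides = np.maximum(1, rng.poisson(6.0, size=n_proteins))
    peptides[:n_single_peptide] = 1
    index = pd.Index([f"P{i:05d}" for i in range(n_proteins)], name="protein")
    table = ProteinGroupTable(
        intensities=pd.DataFrame(intens, index=index, columns=sample_names),
        meta=pd.DataFrame(
            {
                "accession": index,
                "gene": [f"G{i}" for i in range(n_proteins)],
                "unique_peptides": peptides,
                "reverse": np.zeros(n_proteins, dtype=bool),
                "contaminant": np.zeros(n_proteins, dtype=bool),
            },
            index=index,
        ),
        samples=samples,
    )
    truth = {
        "baseline": mu,
        "residual_sd": sd_g,
        "sample_shifts": shifts,
        "variance_factors": dict(zip(sample_names, vfac)),
        "spikes": list(spikes),
    }
    return table, truth
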