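"""Ground-truth recovery: simulate a trial, analyse it, compare.

Generates a noiseless feeding trial with configured growth targets,
per-fatty-acid digestibilities and ALA fate fractions, then pushes the
synthetic carcass compositions back through the mass-balance engine and
confirms the prescribed fates are recovered.
"""

import numpy as np

from famba import MassBalanceInput, fer, mass_balance, sgr, simulate_trial
from famba.synthetic import TrialConfig

cfg = TrialConfig(tank_cv=0.0, system_effect=0.0, faeces_cv=0.0)
ds = simulate_trial(cfg, seed=1)

tank = ds.tanks[-1]  # a TOFX tank
print(f"tank {tank.tank_id}: simulated SGR {sgr(tank):.2f} %/d "
      f"(target {cfg.sgr_targets[tank.diet]}), FER {fer(tank):.2f} "
      f"(target {cfg.fer_targets[tank.diet]})")

res = mass_balance(
    MassBalanceInput(
        feed=cfg.feed_profiles[tank.diet],
        fi_g=tank.fi_g,
        ad=ds.fa_ad[tank.diet],
        initial_weight_g=tank.wi_g,
        initial_profile=ds.initial_carcass,
        final_weight_g=tank.wf_g,
        final_profile=ds.final_carcass[tank.tank_id],
        days=tank.days,
    )
)
truth = ds.ground_truth["tanks"][tank.tank_id]["flux"]
cols = ["accumulated", "oxidized", "bioconverted"]
err = np.abs(res.components.loc[truth.index, cols].to_numpy() - truth[cols].to_numpy()).max()
print("\nRecovered ALA partition (umol/fish):")
print(res.components.loc["18:3n-3", ["net_intake"] + cols].round(1))
print(f"\nmax |recovered - prescribed| over the whole pathway: {err:.2e} umol")
print("The balance inverts the generator exactly: the analysis stack is "
      "self-consistent.")
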