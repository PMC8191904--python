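"""Short versus long cold spells: spike or suppression on rewarming.

A 10-day cold step barely dents the methanogen community, so the VFA that
accumulated while uptake was slow is consumed in a burst once temperature
recovers (an emission spike).  A 300-day cold step starves out the
warm-adapted groups; after rewarming, emissions stay low for weeks while the
community regrows.
"""

import dataclasses

import slurrygas as sg
from slurrygas.experiments import temperature_regime_experiment

base = sg.default_scenario()
base = base.replace(management=dataclasses.replace(base.management, f_resid=0.95))

for dur in (10.0, 300.0):
    res = temperature_regime_experiment(
        base, regime={"kind": "step-drop", "base": 20.0, "low": 5.0,
                      "step_duration": dur})
    print(f"cold step {dur:5.0f} d : pre-step rate {res['pre_step_rate']:7.1f} g/d, "
          f"rewarming peak {res['spike_rate']:7.1f} g/d "
          f"(x{res['spike_ratio']:.2f}), "
          f"recovery of pre-step rate after {res['recovery_time_days']:.0f} d")
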