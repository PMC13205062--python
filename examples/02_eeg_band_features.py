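"""EEG band-power features across the three fatigue stages.

Extracts relative band powers and the beta/(theta+alpha) ratio from
30-second windows of the preprocessed prefrontal EEG and averages them per
stage.  In the active-fatigue scenario the ratio follows an inverted U:
it rises from non-fatigue to moderate fatigue (compensatory engagement)
and falls again under severe fatigue.
"""
import warnings

from fatigue3 import make_scenario, simulate_session
from fatigue3.eeg import eeg_feature_table

warnings.filterwarnings("ignore")

spec = make_scenario("active", seed=1)
recording, truth = simulate_session(spec)
table = eeg_feature_table(recording, truth.timeline)

stage_means = table.groupby("stage")[
    ["rpl_delta_chavg", "rpl_beta_chavg", "eta_chavg"]
].mean().loc[["NonF", "ModF", "SevF"]]
print(stage_means.round(3))
# eta_chavg rising NonF -> ModF then falling ModF -> SevF is the
# inverted-U engagement signature; rpl_delta declining tracks the
# programmed slow-wave schedule.
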