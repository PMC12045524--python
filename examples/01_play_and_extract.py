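"""Play one session headlessly and extract the four skill metrics.

Runs the time-optimal bang-bang controller (always lands) and a default
stochastic participant, then prints their session summaries.
"""

from supergee import TaskConfig, run_session
from supergee.controller import BangCoastBangPolicy, ControllerParams, IdealBangBangPolicy
from supergee.metrics import extract_session_metrics, summarize_session

cfg = TaskConfig()

for name, policy in [
    ("ideal bang-bang", IdealBangBangPolicy(cfg)),
    ("typical participant", BangCoastBangPolicy(ControllerParams())),
]:
    session = run_session(cfg, policy, rng_seed=7)
    summary = summarize_session(extract_session_metrics(session.trial_logs, cfg))
    print(f"{name}:")
    print(f"  successes          {summary.n_success}/{summary.n_trials}")
    print(f"  mean time in target {summary.mean_tint:8.1f} ms")
    print(f"  mean response time  {summary.mean_rt:8.1f} ms (absolute clock)")
    print(f"  mean reversal time  {summary.mean_tr:8.1f} ms")
    print(f"  mean scaling ratio  {summary.mean_sr:8.2f}")

# Time in target is cumulative dwell inside the target planet per trial
# (higher = better skill); response time is when the cursor first leaves
# the start planet after the 1.5 s hold; the scaling ratio compares
# braking to thrust duration (1 = balanced).
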