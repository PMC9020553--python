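"""Simulate one participant session and inspect its ground truth.

A session is 60 trials (30 eyes-cued, 30 mouth-cued; 10 actors x 3 emotions,
fully balanced).  Each trial is 1 s of fixation cross followed by 1.5 s of
face stimulus; with a participant-specific probability the participant makes
one saccade from the cued facial region to the other one.
"""
import numpy as np

import gazeorient as go

params = go.ParticipantParams(participant="demo", p_shift_to_eyes=0.8,
                              p_shift_from_eyes=0.4)
session = go.simulate_session(params, np.random.default_rng(42))

rec = session.recording
print(f"samples: {len(rec)} at {rec.rate:.0f} Hz "
      f"({rec.t[-1] + 1 / rec.rate:.0f} s)")
print(f"trials: {len(session.trials)}; "
      f"conditions: {session.trials['condition'].value_counts().to_dict()}")
print(f"emotions: {session.trials['emotion'].value_counts().to_dict()}")

truth = session.truth
shifted = truth[truth["shift_made"]]
print(f"\ntrue gaze shifts: {len(shifted)}/60")
by_cond = truth.groupby("condition")["shift_made"].mean()
print(f"shift rate by condition:\n{by_cond.to_string()}")
print(f"mean true latency: {1000 * shifted['latency'].mean():.0f} ms")
print(f"mean true peak velocity: {shifted['peak_velocity'].mean():.0f} deg/s "
      "(raised-cosine profile: V_p = 2A/D)")
# The shift rates approach the configured probabilities (0.8 to eyes on
# mouth-cued trials, 0.4 away from eyes on eyes-cued trials) as trials grow.
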