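"""From 3-minute wearable stress scores to validity-filtered stress durations.

Simulates one physician-day of scores with a stressful first work hour and
a sensor-off gap, then applies the 20-minute hourly validity rule.
"""

import numpy as np
import pandas as pd

from inboxstress import hrv_stress as hs

rng = np.random.default_rng(0)
t = np.arange(0, 24 * 60, 3)  # one sample per 3 minutes
hour = t / 60
# stressed mostly in the first work hour (8:30-9:30), calm otherwise
p_stress = np.where((hour >= 8.5) & (hour < 9.5), 0.7, 0.15)
score = np.where(rng.random(len(t)) < p_stress, rng.uniform(55, 95, len(t)), rng.uniform(5, 50, len(t)))
samples = pd.DataFrame(
    {
        "timestamp": pd.Timestamp("2023-03-06") + pd.to_timedelta(t, unit="m"),
        "physician_id": "dr_a",
        "score": score.round(1),
        "activity_flag": rng.random(len(t)) < 0.05,
    }
)
# device off 14:00-15:10 - the 14:30 bin keeps <20 valid minutes
samples = samples[~((hour >= 14.0) & (hour < 15.17))]

hourly = hs.hourly_stress(samples)
kept, _, report = hs.apply_validity_filters(hourly)
print(f"hours kept {len(kept)}/{len(hourly)}; removal report: {report[0].as_dict()}")
first = kept[pd.to_datetime(kept['bin_start']).dt.strftime('%H:%M') == "08:30"].iloc[0]
print(
    f"first work hour: {first['stress_minutes']:.0f} stress min of {first['valid_minutes']:.0f} valid"
    f" -> {hs.round_percent(hs.stress_fraction(first['stress_minutes'], first['valid_minutes'])):.0f}% stress duration"
)
# Scores >50 count as medium/high stress; 25-50 is ordinary arousal and
# <25 rest, both valid but not stressful. Hours with under 20 valid
# minutes are excluded so sparse hours cannot masquerade as calm or
# stressful ones.
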