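#!/usr/bin/env python
"""Exercise the audio measurement pipeline on a synthesized session.

Renders a session recording — model-synthesized cries and phees at
scheduled onsets over pink noise at 20 dB SNR, 96 kHz — and runs the
full measurement chain: envelope-threshold syllable detection, dominant
frequency per syllable, grouping into multisyllabic calls, and
contingency scoring of simulated parental responses.

Writes: results/acoustics_detection.csv, results/acoustics_summary.json
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from vocaldev import acoustics as ac
from vocaldev import synthetic_data as sd

RESULTS = Path(__file__).resolve().parent.parent / "results"
FS = 96_000


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    schedule = [(3.0, "cry"), (6.0, "phee"), (7.4, "phee"), (10.5, "phee"),
                (14.0, "cry"), (17.5, "phee")]
    audio, truth = sd.generate_audio_session(schedule, fs=FS, snr_db=20.0,
                                             seed=7, duration_s=21.0)

    sylls = ac.detect_syllables(audio, FS, baseline=(0.0, 2.5))
    rows = []
    for s in sylls:
        seg = audio[int(s.onset * FS):int(s.offset * FS)]
        s.dominant_frequency = ac.dominant_frequency(seg, FS)
        # type from the schedule entry it overlaps (detection is untyped)
        hit = truth[(truth.onset_s < s.offset) & (truth.offset_s > s.onset)]
        s.call_type = hit.call_type.iloc[0] if len(hit) else "unknown"
        rows.append({"onset_s": s.onset, "offset_s": s.offset,
                     "type": s.call_type,
                     "dom_freq_khz": s.dominant_frequency})
    det = pd.DataFrame(rows)
    det.to_csv(RESULTS / "acoustics_detection.csv", index=False)
    print(f"scheduled {len(truth)} calls, detected {len(det)} syllables")
    print(det.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    calls = ac.group_calls(sylls)
    print(f"\ngrouped into {len(calls)} whole calls "
          f"(phee pair at 6.0/7.4 s merges: gap 0.4 s < 0.5 s)")

    # simulated parent responds 2 s after each phee except the last
    phee_offsets = [c.offset for c in calls if c.call_type == "phee"]
    parent_onsets = np.array([t + 2.0 for t in phee_offsets[:-1]])
    F = ac.contingency_score(calls, parent_onsets)
    print(f"contingency proportion F = {F:.3f}")

    with open(RESULTS / "acoustics_summary.json", "w") as fh:
        json.dump({"n_scheduled": len(truth), "n_detected": len(det),
                   "n_calls_grouped": len(calls), "F": F}, fh, indent=1)


if __name__ == "__main__":
    main()
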