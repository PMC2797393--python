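"""Recover pitch and twist from noisy synthetic segments.

Generates 200 extended-state side views (snr 0.1), preprocesses them,
classifies into ~15-member classes, and runs the two-stage grid search
(coarse 3.2 A / 2 deg, fine 0.5 A / 0.5 deg) on the class averages.
Takes a couple of minutes on one CPU.
"""

from helifil import generate_dataset, search_helical_params
from helifil.imagio import RunConfig
from helifil.preprocess import preprocess_stack
from helifil.msa import eigen_decompose, classify, class_average
from helifil.geometry import protomers_per_turn


cfg = RunConfig(seed=1, options={
    "n_segments": 200, "box_size": 64, "pixel_size": 4.0, "snr": 0.1,
    "states": [{"name": "extended", "fraction": 1.0}],
    "tilt_sd": 5.0, "inplane_jitter": 5.0, "defocus": None})
stack, meta = generate_dataset(cfg)
stack = preprocess_stack(stack)

eig = eigen_decompose(stack, 10)
cls = classify(stack, eig, n_classes=len(stack) // 15, seed=2)
averages = [ca.image for ca in class_average(stack, cls)]

refined, coarse = search_helical_params(averages, stack.pixel_size)
p0, t0, _ = coarse.global_minimum()
print(f"coarse minimum:  pitch {p0:6.1f} A, twist {t0:4.1f} deg")
print(f"refined:         pitch {refined.params.pitch:6.2f} A, "
      f"twist {refined.params.twist:5.2f} deg "
      f"({protomers_per_turn(refined.params.twist)[0]} protomers/turn)")
print(f"ground truth:    pitch  110.00 A, twist 40.50 deg (8.9 protomers/turn)")
print("\nAt this reduced scale (200 segments) the twist lands on the "
      "generating value and the pitch within about one fine grid step; "
      "the full-scale study (500 segments, tests/test_acceptance.py) "
      "recovers both to within 0.5 A / 0.5 deg.")
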