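"""TM-score oracle: superpose two CA traces and score their similarity.

Builds an ideal two-helix fold, makes a hinge-perturbed copy, and
computes the TM-score for the index correspondence.  TM-scores live in
(0, 1]; above ~0.5 two chains share a fold, and the hinge rotation should
pull the score well below the near-1 value of a lightly noised copy.
"""

from foldvec.synthetic import FoldSpec, generate_fold, perturb_structure
from foldvec.tmscore import tm_score

spec = FoldSpec(elements=[("helix", 30), ("coil", 5), ("helix", 30)],
                packing_seed=0, offsets=[[0, 0, 0], [24.0, 6.0, 2.0]])
fold = generate_fold(spec, rng_seed=0)

noisy = perturb_structure(fold, coordinate_noise_sd=0.3, rng_seed=1)
hinged = perturb_structure(fold, hinge_count=1, hinge_angle_sd=60.0, rng_seed=2)

for name, variant in [("0.3 A noise", noisy), ("60 deg hinge", hinged)]:
    res = tm_score(fold, variant)
    print(f"{name:12s}  tm_query={res.tm_query:.3f}  tm_target={res.tm_target:.3f}"
          f"  tm_max={res.tm_max:.3f}  rmsd={res.superposition.rmsd:.2f} A")

print("\nThe noised copy stays near 1 (same fold, tiny distortions); the "
      "hinged copy scores lower because a rigid superposition cannot track "
      "the domain movement.")
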