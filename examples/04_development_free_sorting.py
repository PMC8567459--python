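"""Developmental change in free classification, computed exactly.

Six unlabeled stimuli can be sorted by overall similarity (spatially
compact groups), by rough one-dimensional similarity, or by exact
identity on one dimension.  Modeling age as the narrowness of the
learned covariance components (children's components are wider — less
category experience), the exact posterior over all 203 partitions shifts
from overall-similarity sorting in young children to strict
one-dimensional identity in adults.
"""

from refreshcat.experiments import free_classification_development

res = free_classification_development(seed=0)
print(f"{'age':8s} {'overall':>9s} {'1d-simil':>9s} {'1d-ident':>9s} "
      f"{'other':>7s}  modal sort")
for age in ("3yo", "4yo", "5yo", "adult"):
    m = res["ages"][age]
    print(f"{age:8s} {m['overall_similarity']:9.3f} "
          f"{m['one_dimensional_similarity']:9.3f} "
          f"{m['one_dimensional_identity']:9.3f} {m['other']:7.3f}  "
          f"{m['modal_type']}")
print("\nNarrower components make exact dimension matches ever more "
      "diagnostic, so the modal sort migrates from family resemblance "
      "to dimensional identity with age.")
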