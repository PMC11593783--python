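"""Duplicated control-region structure and degeneration.

Builds a control region carrying the full complement of conserved boxes
(ETAS, Central and CSB domains) plus a tandem-repeat array, then degrades
a second copy the way accipitrid pseudo-control-regions decay: point
substitutions, loss of conserved boxes and a 3' repeat expansion. The
profile of each copy and the resulting gene-order class are printed.
"""

import mitobias as mb

lib = mb.BoxLibrary.load()
plan = mb.CRPlan(length=1400, repeat=("TATTA", 8))
cr1, layout = mb.build_control_region(plan, lib, seed=11)

degrade = mb.DegradePlan(sub_rate=0.35, indel_rate=0.02,
                         delete_boxes=frozenset(plan.boxes),
                         expand_repeat=("TTTTA", 14))
cr2 = mb.degrade_cr(cr1, degrade.sub_rate, degrade.indel_rate,
                    degrade.delete_boxes, degrade.expand_repeat,
                    layout=layout, seed=12)

for which, seq in (("CR1", cr1), ("CR2", cr2)):
    profile = mb.profile_cr(seq, which, lib, min_period=4, min_copies=3.0)
    boxes = ", ".join(f"{h.box}@{h.start}" for h in profile.hits)
    print(f"{which}: {len(seq)} bp; domains {sorted(profile.domains_present)}")
    print(f"  boxes: {boxes or 'none'}")
    for r in profile.repeats:
        print(f"  repeat: {r.motif} x{r.copies:.1f} at {r.start}-{r.end} "
              f"({r.composition_class}, purity {r.purity:.2f})")

identity = mb.pairwise_identity(cr1, cr2)
print(f"\nCR1-CR2 identity: {identity:.1f}%")
print("verdict: GO-II (concerted duplicates) requires all CR2 domains and "
      f"identity >= 60%; here CR2 is degenerate -> GO-IV territory")
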