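"""Worked clinical example: what design bias means for one patient.

A rheumatoid-arthritis classification rule was validated at sensitivity =
specificity = 90% (DOR 81) in a study using both an inadequate sample size
and a case-control design.  Removing the combined 4.2-fold overestimation
(1.9 x 2.2) implies a DOR of about 19 (sens = spec = 81%), and the
post-test probability for a rule-positive patient with 10% pre-test risk
drops from 50% to 32%.
"""
import json
from pathlib import Path

from metaepi import (
    dor_from_sens_spec,
    equal_sens_spec_for_dor,
    posttest_probability,
    relative_dor,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    reported = 0.90
    dor = dor_from_sens_spec(reported, reported)
    factor = 1.9 * 2.2  # inadequate sample size x case-control design
    adjusted_dor = dor / factor
    adjusted = equal_sens_spec_for_dor(adjusted_dor)
    biased = posttest_probability(0.10, reported, reported, "positive")
    unbiased = posttest_probability(0.10, adjusted, adjusted, "positive")
    print(f"reported sens = spec = {reported:.0%}  ->  DOR = {dor:.0f}")
    print(f"combined overestimation factor: {factor:.1f}")
    print(f"bias-adjusted DOR = {adjusted_dor:.1f}"
          f"  ->  sens = spec = {adjusted:.0%}")
    print(f"post-test probability at 10% pre-test risk:")
    print(f"  biased accuracy:   {biased.posttest_prob:.0%}"
          f" (LR+ = {biased.lr:.1f})")
    print(f"  adjusted accuracy: {unbiased.posttest_prob:.0%}"
          f" (LR+ = {unbiased.lr:.1f})")
    assert relative_dor(dor, adjusted_dor) == factor
    (OUT / "worked_example.json").write_text(json.dumps({
        "reported_dor": dor,
        "overestimation_factor": factor,
        "adjusted_dor": adjusted_dor,
        "adjusted_sens_spec_percent": round(100 * adjusted),
        "posttest_biased": biased.posttest_prob,
        "posttest_adjusted": unbiased.posttest_prob,
    }, indent=2))
    print(f"wrote {OUT / 'worked_example.json'}")


if __name__ == "__main__":
    main()
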