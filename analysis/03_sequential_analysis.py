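#!/usr/bin/env python
"""Two-stage primary analysis: published phase counts and design checks.

Runs the per-phase one-sided pooled two-proportion tests on the printed
correct-negative counts for both device settings, combines them with the
prespecified inverse-normal weights, and compares against the adjusted
final-look level.  Also re-derives the spending boundary for the study's
information fractions, the interim futility/reassessment decision, and
the sample-size arithmetic.
"""

import dataclasses
import json
from pathlib import Path

from dermtriage import study
from dermtriage.sequential import (
    DesignSpec,
    boundary_solve,
    interim_assessment,
    lesions_to_patients,
    run_two_stage_from_counts,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    design = DesignSpec()
    payload = {}
    for setting in ("ai_a", "ai_b"):
        phase1 = (study.PHASE1_CORRECT[setting], study.PHASE1_N,
                  study.PHASE1_CORRECT["soc"], study.PHASE1_N)
        phase2 = (study.PHASE2_CORRECT[setting], study.PHASE2_N,
                  study.PHASE2_CORRECT["soc"], study.PHASE2_N)
        result = run_two_stage_from_counts(phase1, phase2, design)
        payload[setting] = {
            "phase1_z": result.phase1.z,
            "phase1_p": result.phase1.p_one_sided,
            "phase2_z": result.phase2.z,
            "phase2_p": result.phase2.p_one_sided,
            "combined_z": result.combined_z,
            "combined_p": result.combined_p,
            "decision": result.decision,
        }
        print(f"{setting}: z1={result.phase1.z:.3f}, z2={result.phase2.z:.3f}, "
              f"combined p={result.combined_p:.3g} -> {result.decision} "
              f"at {design.final_nominal_alpha}")

    levels = boundary_solve(design.information_fractions, design.overall_alpha)
    payload["boundary"] = {"interim": levels[0], "final": levels[1]}
    print(f"solved boundary: interim nominal {levels[0]:.3g}, "
          f"final nominal {levels[1]:.5f} (study used {design.final_nominal_alpha})")

    interim = interim_assessment(
        (study.PHASE1_CORRECT["ai_a"], study.PHASE1_N,
         study.PHASE1_CORRECT["soc"], study.PHASE1_N),
        design,
    )
    payload["interim"] = dataclasses.asdict(interim)
    print(f"interim: {interim.decision} "
          f"(conditional power {interim.conditional_power:.3f})")

    payload["patients_for_planned_lesions"] = lesions_to_patients(
        study.PLANNED_LESIONS, design.lesions_per_patient, design.dropout
    )
    print(f"{study.PLANNED_LESIONS} lesions -> "
          f"{payload['patients_for_planned_lesions']} patients")
    (OUT / "sequential_analysis.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {OUT / 'sequential_analysis.json'}")


if __name__ == "__main__":
    main()
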