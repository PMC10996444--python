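#!/usr/bin/env python
"""Cost impact of AI triage: derived avoided activity and published counts.

Derives avoided teledermatology reviews, face-to-face assessments and
biopsies from a full-pathway lesion table under the triage assumption
(premalignant-or-benign device output ends the urgent pathway), prices
them with the published unit costs, and extrapolates per 1,000 patients.
"""

import dataclasses
import json
from pathlib import Path

from dermtriage.cost import cost_impact, derive_avoided_activity
from dermtriage.fixtures import make_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    lesions, _ = make_fixture("study_cost")
    avoided = derive_avoided_activity(lesions, "ai_a")
    impact = cost_impact(avoided)
    print(f"avoided activity: {avoided.reviews_avoided} reviews, "
          f"{avoided.f2f_avoided} face-to-face, {avoided.biopsies_avoided} "
          f"biopsies across {avoided.pathway_patients} pathway patients")
    print(f"savings: reviews £{impact.review_saving}, "
          f"F2F £{impact.f2f_saving}, biopsies £{impact.biopsy_saving}")
    print(f"total £{impact.total_saving}, {impact.total_hours} specialist h "
          f"({impact.component_hours()})")
    print(f"per 1,000 pathway patients: £{impact.per_1000_saving}, "
          f"{impact.per_1000_hours} h")
    payload = {
        "avoided": dataclasses.asdict(avoided),
        "impact": impact.as_dict(),
    }
    (OUT / "cost_impact.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {OUT / 'cost_impact.json'}")


if __name__ == "__main__":
    main()
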