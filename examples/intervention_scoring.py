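"""Score an intervention from its per-phase trial counts.

An intervention studied in three phase-1, four phase-2, seven phase-3, and
one phase-4 trial (15 trials) scores 1 + 2 + 3 + 4 for the occupied phases
plus 0.001 per trial: 10.015. A combined "Phase 2/Phase 3" label counts at
the higher phase.
"""

from trialpubs import TrialRecord, build_intervention_table

plan = [("Phase 1", 3), ("Phase 2", 4), ("Phase 3", 7), ("Phase 4", 1)]
trials = []
i = 0
for label, count in plan:
    for _ in range(count):
        i += 1
        trials.append(
            TrialRecord(
                nct_id=f"NCT0900{i:04d}",
                brief_title=f"Trial {i} of mrna-1273 for COVID-19",
                phase_labels=[label],
                intervention_names=["mrna-1273"],
            )
        )

(group,) = build_intervention_table(trials)
print(f"intervention:       {group.canonical_name}")
print(f"trials:             {len(group.trial_ids)}")
print(f"phase counts:       { {k.value: v for k, v in sorted(group.phase_counts.items())} }")
print(f"significance score: {group.significance_score}")
# score - 0.001 x trial_count recovers the occupied-phase value sum exactly
print(f"base component:     {round(group.significance_score - 0.001 * len(group.trial_ids), 3)}")
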