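"""Generate a synthetic task-fMRI cohort and apply motion QC.

Draws ROI x time BOLD series for four diagnostic groups under three N-back
load conditions, plus framewise-displacement traces, then applies the
exclusion rule (FD > 0.5 mm in >= 20% of volumes).
"""

import cereconn as cc

# scaled-down cohort so the example runs in seconds; the defaults emulate
# the full study (group sizes 23/34/20/21, R=165, T=137)
config = cc.CohortConfig(
    group_sizes={"SCZ": 6, "SCZ-SIB": 8, "CON": 5, "CON-SIB": 5},
    R=60, T=137, seed=1,
)
series, traces = cc.generate_roi_timeseries(config)

decisions = [cc.qc_exclude(t) for t in traces]
excluded = [d.subject_id for d in decisions if d.exclude]

print(f"subjects: {len(traces)}, series (subject x condition): {len(series)}")
print(f"one series shape (ROIs x volumes): {series[0].data.shape}")
print(f"excluded for motion: {len(excluded)} -> {excluded}")
print("kept graphs would number", (len(traces) - len(excluded)) * 3)
# Excluded subjects emulate the attrition from a raw cohort to the subjects
# with usable data in all three task conditions.
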