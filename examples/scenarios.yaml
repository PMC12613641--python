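# Prevention-effect scenario grid: 28-day VAP cumulative incidence in the
# control arm and the relative reduction in the intervention arm.
# Load with vaptrials.load_scenarios("examples/scenarios.yaml").
- {id: 1, p_soc: 0.155, reduction: 0.20}
- {id: 2, p_soc: 0.155, reduction: 0.25}
- {id: 3, p_soc: 0.155, reduction: 0.30}
- {id: 4, p_soc: 0.155, reduction: 0.35}
- {id: 5, p_soc: 0.155, reduction: 0.40}
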