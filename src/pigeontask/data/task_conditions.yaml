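# Task parameters of the three study cohorts, one row per block.
# step_mean is the unsigned per-step drift magnitude μ (the sign is drawn
# 50/50 per trial); two-element means are the low/high magnitudes of
# trial-mixed blocks or the (first, second) magnitudes of changepoint blocks.
- {cohort: 1, block: 1, step_mean: 0.05, step_std: 0.15, coins_correct: 1, coins_error: 0,  steps_error_penalty: 0}
- {cohort: 1, block: 2, step_mean: 0.05, step_std: 0.15, coins_correct: 1, coins_error: -4, steps_error_penalty: 0}
- {cohort: 1, block: 3, step_mean: 0.05, step_std: 0.15, coins_correct: 1, coins_error: 0,  steps_error_penalty: 30}
- {cohort: 1, block: 4, step_mean: 0.15, step_std: 0.15, coins_correct: 1, coins_error: 0,  steps_error_penalty: 0}
- {cohort: 1, block: 5, step_mean: 0.15, step_std: 0.15, coins_correct: 1, coins_error: -4, steps_error_penalty: 0}
- {cohort: 1, block: 6, step_mean: 0.15, step_std: 0.15, coins_correct: 1, coins_error: 0,  steps_error_penalty: 30}
- {cohort: 2, block: 1, step_mean: [0.05, 0.15], snr_mode: trial_mixed, step_std: 0.15, coins_correct: 1, coins_error: 0,  steps_error_penalty: 0}
- {cohort: 2, block: 2, step_mean: [0.05, 0.15], snr_mode: trial_mixed, step_std: 0.15, coins_correct: 1, coins_error: -4, steps_error_penalty: 0}
- {cohort: 2, block: 3, step_mean: [0.05, 0.15], snr_mode: trial_mixed, step_std: 0.15, coins_correct: 1, coins_error: 0,  steps_error_penalty: 30}
- {cohort: 2, block: 4, step_mean: 0.1, step_std: 0.15, coins_correct: 1, coins_error: 0,  steps_error_penalty: 0}
- {cohort: 2, block: 5, step_mean: 0.1, step_std: 0.15, coins_correct: 1, coins_error: -4, steps_error_penalty: 0}
- {cohort: 2, block: 6, step_mean: 0.1, step_std: 0.15, coins_correct: 1, coins_error: 0,  steps_error_penalty: 30}
- {cohort: 3, block: 1, step_mean: 0.01, step_std: 0.05, coins_correct: 1, coins_error: -1, steps_error_penalty: 0}
- {cohort: 3, block: 2, step_mean: 0.02, step_std: 0.05, coins_correct: 1, coins_error: -1, steps_error_penalty: 0}
- {cohort: 3, block: 3, step_mean: [0.01, 0.02], snr_mode: trial_mixed, step_std: 0.05, coins_correct: 1, coins_error: -1, steps_error_penalty: 0}
- {cohort: 3, block: 4, step_mean: [0.01, 0.02], snr_mode: changepoint, changepoint_direction: low_to_high, step_std: 0.05, coins_correct: 1, coins_error: -1, steps_error_penalty: 0}
- {cohort: 3, block: 5, step_mean: [0.02, 0.01], snr_mode: changepoint, changepoint_direction: high_to_low, step_std: 0.05, coins_correct: 1, coins_error: -1, steps_error_penalty: 0}
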