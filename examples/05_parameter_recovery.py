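"""Small parameter-recovery study for the convolution model.

Each replicate simulates a fresh survey under the default conditions and
fits the convolution model; the table counts how often the 95% credible
interval covers each nonzero true coefficient.  (The package's full
validation uses 20 replicates at 20,000 iterations; this demo runs 5
shorter replicates to finish in about a minute.)
"""

from anemiamap import coverage_study

table = coverage_study(n_replicates=5, seed=3, n_iter=8000, burn_in=1500)
print("Coverage of nonzero true coefficients (5 replicates):")
print(table.to_string(index=False))
print("\n'covered' near the replicate count indicates calibrated intervals;")
print("'mean_estimate' near 'true_value' indicates unbiased point recovery.")
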