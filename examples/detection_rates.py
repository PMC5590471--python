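"""Small detection-rate study: power and false positives of the F test.

Runs the random-network simulation harness on a reduced grid (50
metabolites, two noise levels, two omission counts, 100 replicates per
cell) and prints the true/false-positive rates.  TP should rise with more
omitted reactions and fall with noise; FP should stay low throughout.
"""

from fluxdiag import SimScenario, run_detection_grid

scenarios = [
    SimScenario(m=50, n_internal=30, n_exchange=25, n_omit=no, cov=cov,
                replicates=100)
    for no in (2, 5) for cov in (0.01, 0.2)
]
df = run_detection_grid(scenarios, tests=("f",), seed=5)
print(df[["m", "n_omit", "cov", "test", "tp", "fn", "fp", "tn",
          "replicates"]].to_string(index=False))
print("\nEach row: rejection rates of the F test with the true omitted")
print("reactions as candidates (tp/fn) and with decoy candidates (fp/tn).")
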