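"""A reduced-scale run of the simulation-study benchmark.

Runs three cells of the study grid (varying the number of pre-selected
markers) at 10 replicates each and prints the Table-style summary: median
and IQR of the test-sample Uno concordance for the boosted combination,
alongside the concordance achieved by the true data-generating
combination.  At full scale (100 replicates) the medians stabilise; see
scripts/acceptance.py.
"""

from cboost import BoostingConfig, STUDY_M_STOP, StudySetting, run_simulation_study

settings = [
    StudySetting(n_train=100, p_select=5, censoring=0.5),
    StudySetting(n_train=100, p_select=10, censoring=0.5),
    StudySetting(n_train=100, p_select=30, censoring=0.5),
]
result = run_simulation_study(
    settings,
    n_runs=10,
    seed=11,
    boosting=BoostingConfig(m_stop=STUDY_M_STOP),
    progress=True,
)
print()
print(result.summary().to_string(index=False))
print(
    "\nMore pre-selected markers means more noise components competing for\n"
    "updates from a fixed training sample, so at full replication the\n"
    "boosted test concordance decreases from p=5 towards p=30 (at the 10\n"
    "replicates shown here the small-p ordering is still within noise);\n"
    "the true combination's concordance is unaffected by estimation."
)
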