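"""The mRNA-count experiment: WT vs knockout, two replicate experiments.

Simulates 3 embryos per genotype per experiment, filters cells below 10
mRNAs, and compares per-cell counts and neighbor-cluster Fano factors with
the Mann-Whitney rank test.
"""

from embryoquant import SimConfig
from embryoquant.pipeline import run_experiment_counts

cfg = SimConfig(n_cols=10, n_rows=6)  # ko_deg_factor defaults to 1.5
report = run_experiment_counts(cfg, seed=4, n_embryos=3, n_experiments=2)

for exp in report["experiments"]:
    c, f = exp["counts"], exp["fano"]
    print(f"experiment {exp['experiment']}: "
          f"median count WT {c['median_wt']:.0f} vs KO {c['median_ko']:.0f} "
          f"(p = {c['p_value']:.2e}); "
          f"median cluster FF WT {f['median_wt']:.2f} vs KO "
          f"{f['median_ko']:.2f} (p = {f['p_value']:.3f})")
# Slower mRNA decay in the knockout raises the per-cell count by about the
# degradation factor; the count comparison is decisive in every replicate,
# while the FF difference is the smaller, noisier effect.
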