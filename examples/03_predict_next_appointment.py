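"""Benchmark regressors on predicting the weeks to the next appointment.

Chains corpus -> extraction -> scoring -> features, splits by worker (a
worker's records never straddle train and test), then compares the built-in
boosted trees with scikit-learn comparators on RMSLE / R-squared / MAE plus
worker-disjoint cross-validated R-squared.
"""

from ohpp import (
    GeneratorConfig,
    Lexicon,
    assemble_features,
    build_profile,
    default_registry,
    evaluate_models,
    generate_cohort,
    results_to_frame,
    score_profile,
    scores_to_frame,
    split_by_worker,
)

lexicon = Lexicon.default()
corpus = generate_cohort(GeneratorConfig(n_workers=300, seed=7))
scored = [score_profile(build_profile(a.sentences, lexicon, metadata=a.__dict__)) for a in corpus]
table = assemble_features(scores_to_frame(scored))
plan = split_by_worker(table, test_fraction=0.2, seed=7, k_folds=5)
print(f"{len(table.frame)} records: {len(plan.train_index)} train / {len(plan.test_index)} test")

registry = default_registry(seed=7, include_optional=False)
results = evaluate_models(registry, table, plan, scenario="interval")
print(results_to_frame(results).to_string(index=False))
# lower RMSLE/MAE and higher R2 are better; CV-R2 shows stability across folds
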