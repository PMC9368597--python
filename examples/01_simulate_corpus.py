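"""Generate a small synthetic OHPP corpus and look at what it contains.

The generator emulates an automotive plant's occupational-health records:
restriction sentences written per appointment, worker demographics (about
23% female, per-gender seniority distributions), production areas, and
timelines where severity shortens the sampled time to the next appointment.
"""

import collections

from ohpp import GeneratorConfig, generate_cohort

config = GeneratorConfig(n_workers=80, seed=42)
corpus = generate_cohort(config)

workers = {a.worker_id for a in corpus}
female = sum(1 for w in workers if next(a.gender for a in corpus if a.worker_id == w) == "F")
print(f"{len(corpus)} appointments for {len(workers)} workers "
      f"({100 * female / len(workers):.1f}% female)")

counts = collections.Counter(collections.Counter(a.worker_id for a in corpus).values())
print("appointments-per-worker histogram:", dict(sorted(counts.items())))
# the histogram decays with the number of visits and has no mass at 8

example = next(a for a in corpus if a.true_protections and a.true_protections[0][1])
print("\nan appointment with restrictions:")
for s in example.sentences:
    print("  ", s)
print("ground-truth severity scores:",
      {k: round(v, 2) for k, v in example.true_scores.items() if v > 0})
if example.true_interval_weeks:
    print(f"weeks until next appointment: {example.true_interval_weeks:.1f}")
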