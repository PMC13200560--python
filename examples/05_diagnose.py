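"""Automated diagnosis by row-sum matching.

Three illustrative patient vignettes (written for this package) are
encoded as 0/1 response vectors; multiplying the matrix by the vector
and comparing against the row sums finds every phenotype whose
characteristics are all present.  Both definitive and probable diagnoses
are reported — the engine applies no exclusivity rule, because "not
better accounted for" is deliberately outside the matrix.
"""

from ichd_matrix import ResponseVector, bundled_matrix, contradiction_check, diagnose

m = bundled_matrix()

cases = {
    "episodic migraine vignette": [
        "greater than 5 episodes", "4 to 72 h", "unilateral",
        "pulsating", "nausea/vomiting",
    ],
    "cluster headache vignette": [
        "greater than 5 episodes", "severe", "unilateral",
        "orbital or supraorbital or temporal pain", "15 to 180 min",
        "every other day to 8 per day", "lacrimation",
    ],
    "new daily persistent headache vignette": [
        "clearly remembered onset", "constant",
        "unremitting within 24 h", "more than 3 months",
    ],
}

for title, characteristics in cases.items():
    v = ResponseVector({c: 1 for c in characteristics})
    for warning in contradiction_check(m, v):
        print(f"  warning: {warning}")
    result = diagnose(m, v)
    print(f"{title}:")
    print(f"  answers marked present: {len(characteristics)}")
    print(f"  diagnosed disorders:    {', '.join(result.diagnosed_disorders)}")
    print(f"  satisfied phenotypes:   {len(result.satisfied_phenotypes)} "
          f"(e.g. {', '.join(result.satisfied_phenotypes[:3])})")
    near = max((s for r, s in result.scores.items()
                if r not in result.satisfied_phenotypes), default=0.0)
    print(f"  best partial-match score among unsatisfied rows: {near:.2f}\n")
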