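"""Independent brute-force oracles, kept free of the package's internals."""


def prob_inadequacy_loop(requirements, absorbed):
    """Fraction of requirement grid points strictly above the absorbed value."""
    above = sum(1 for r in requirements if r > absorbed)
    return above / len(requirements)


def prevalence_curve_loop(intakes, requirements, grid_values):
    """Double-loop predicted prevalence (%) at every absorption grid value."""
    out = []
    for a in grid_values:
        total = 0.0
        for intake in intakes:
            total += prob_inadequacy_loop(requirements, intake * a / 100.0)
        out.append(100.0 * total / len(intakes))
    return out
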