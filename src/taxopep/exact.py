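"""Exact marginals by exhaustive enumeration of joint states.

Independent of the message-passing code: the joint weight of every
assignment of the binary taxon and peptide variables is evaluated directly
from the factor definitions (taxon priors, count-regularized noisy-OR
tables, observation likelihoods) and summed.  Exponential in the number of
variables — intended for validating belief propagation on small graphs.
"""

from __future__ import annotations

import itertools

from .graph import FactorGraph

__all__ = ["brute_force_marginals"]


def brute_force_marginals(
    graph: FactorGraph,
) -> tuple[dict[int, float], dict[str, float]]:
    """Return exact (taxon marginals, peptide marginals).

    Enumerates all 2^(T+P) joint assignments; keep T + P <= ~20.
    """
    taxa = list(graph.taxa)
    seqs = sorted(graph.factors)
    gamma = graph.params.gamma
    taxon_mass = {t: 0.0 for t in taxa}
    pep_mass = {s: 0.0 for s in seqs}
    total = 0.0
    index = {t: i for i, t in enumerate(taxa)}

    for t_state in itertools.product((0, 1), repeat=len(taxa)):
        w_taxa = 1.0
        for present in t_state:
            w_taxa *= gamma if present else 1.0 - gamma
        if w_taxa == 0.0:
            continue
        for p_state in itertools.product((0, 1), repeat=len(seqs)):
            w = w_taxa
            for s, detected in zip(seqs, p_state):
                f = graph.factors[s]
                n = sum(t_state[index[t]] for t in f.parents)
                cond = f.p_det[n] if detected else 1.0 - f.p_det[n]
                obs = f.score if detected else 1.0 - f.score
                w *= f.reg[n] * cond * obs
            total += w
            for t, present in zip(taxa, t_state):
                if present:
                    taxon_mass[t] += w
            for s, detected in zip(seqs, p_state):
                if detected:
                    pep_mass[s] += w

    if total <= 0.0:
        raise ValueError("joint distribution has zero total mass")
    return (
        {t: taxon_mass[t] / total for t in taxa},
        {s: pep_mass[s] / total for s in seqs},
    )
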