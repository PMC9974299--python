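"""Shared helpers for the test suite."""

import mcprobit as m
from mcprobit.multivariate import z_layout


def reduced_theta(theta: m.ThetaMultivariate, keep: list) -> m.ThetaMultivariate:
    """The multivariate model restricted to a subset of variables.

    The reduced z vector picks out the surviving within-group and
    between-group slots from the full parametrization.
    """
    grouping = tuple(theta.grouping[j] for j in keep)
    _, slots = z_layout(grouping)
    full_labels, full_slots = z_layout(theta.grouping)
    out = []
    for slot in slots:
        if slot[0] == "within":
            out.append(theta.z[full_slots.index(slot)])
        else:
            _, a, b = slot
            a2, b2 = sorted((a, b), key=full_labels.index)
            out.append(theta.z[full_slots.index(("between", a2, b2))])
    return m.ThetaMultivariate(
        tuple(theta.thetas[j] for j in keep), tuple(out), grouping
    )
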