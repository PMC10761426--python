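"""Published reference artefacts shipped with the package.

``published_loadings`` returns the 71-variable x 6-factor varimax-rotated
loading matrix of the combined factor analysis from the childhood-obesity
metabotyping study this workflow reproduces, transcribed into a fixture.
It is the worked example for the variable-retention / factor-assignment
rule: applying the rule to these loadings must reproduce the published
factor memberships.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .integrate import ComponentModel, RetentionDecision, apply_retention

FACTOR_COLUMNS = ["F1", "F2", "F3", "F4", "F5", "F6"]


def published_loadings() -> pd.DataFrame:
    """The transcribed combined-FA loading matrix (71 variables x 6 factors).

    Index: metabolite identifier; columns F1..F6 plus ``published_factor``
    (the factor the publication lists the variable under) and the annotation
    ``confidence`` level.
    """
    path = importlib.resources.files("metabotyper") / "data" / "published_loadings.tsv"
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", index_col="variable")
    return df


def published_loadings_model() -> ComponentModel:
    """The published loading matrix wrapped as a ComponentModel (mlfa/varimax)."""
    df = published_loadings()
    loadings = df[FACTOR_COLUMNS].astype(float)
    share = (loadings ** 2).sum(axis=0).to_numpy() / len(loadings)
    return ComponentModel(
        method="mlfa", rotation="varimax",
        variable_ids=list(loadings.index), loadings=loadings,
        variance_share=share, cumulative_variance=float(share.sum()),
        kmo=0.76)


def published_retention(threshold: float = 0.5, gap: float = 0.1
                        ) -> list[RetentionDecision]:
    """Retention/assignment decisions on the published loading matrix."""
    return apply_retention(published_loadings_model(), threshold, gap)


def count_assigned(decisions: list[RetentionDecision], factor: int,
                   prefix: str | None = None) -> int:
    """Count retained variables assigned to ``factor`` (1-based).

    Optionally restrict to variables whose identifier starts with ``prefix``.
    """
    n = 0
    for d in decisions:
        if not d.retained or d.assigned_component != factor - 1:
            continue
        if prefix is not None and not d.variable.startswith(prefix):
            continue
        n += 1
    return n
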