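"""Marker-based cell-composition correction and the diving-group comparison.

Bulk brain samples from different species (or regions) differ in their
glia/neuron proportions, which confounds cross-species comparison of genes
expressed mainly in one cell type.  A two-marker proxy is used: the ratio of
a glial marker (GFAP by default) to a neuronal marker (RBFOX3/NeuN by
default; SNAP25 where RBFOX3 is unannotated, e.g. pig) stands in for the
glia/neuron composition of each sample.  For a gene expressed predominantly
in glia (such as S100B), dividing its RPKM by the sample's glia/neuron ratio
yields expression per unit of glial signal, comparable across samples:

    ratio_s     = RPKM_GFAP,s / RPKM_RBFOX3,s
    corrected_s = RPKM_target,s / ratio_s

Correction is applied only to genes the user designates (a gene expressed in
both neurons and glia, like clusterin, should not be corrected).  Corrected
(or raw) values are then compared between species groups (diving vs
non-diving) with a two-sample t-test, pooled-variance Student by default
with a Welch option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionTable

__all__ = [
    "CompositionProfile",
    "GroupComparison",
    "glia_neuron_ratio",
    "composition_correct",
    "two_group_ttest",
    "read_groups_table",
    "DegenerateVarianceError",
]

DEFAULT_GLIA_MARKER = "GFAP"
DEFAULT_NEURON_MARKER = "RBFOX3"


class DegenerateVarianceError(ValueError):
    """Zero within-group variance with unequal means: t is infinite."""


@dataclass
class CompositionProfile:
    """Two-marker composition proxy for one species' sample."""

    species_id: str
    glia_marker: str
    neuron_marker: str
    glia_rpkm: float
    neuron_rpkm: float

    @property
    def ratio(self) -> float:
        """Glia/neuron marker ratio (GFAP / RBFOX3 by convention)."""
        return self.glia_rpkm / self.neuron_rpkm


@dataclass
class GroupComparison:
    group_a: list[tuple[str, float]]
    group_b: list[tuple[str, float]]
    t_statistic: float
    df: float
    p_two_tailed: float


def glia_neuron_ratio(
    table: ExpressionTable,
    glia_marker: str = DEFAULT_GLIA_MARKER,
    neuron_marker: str = DEFAULT_NEURON_MARKER,
) -> CompositionProfile:
    """Compute a sample's glia/neuron marker ratio from its RPKM table."""
    values = {}
    for role, marker in (("glia", glia_marker), ("neuron", neuron_marker)):
        try:
            v = table.rpkm_of(marker)
        except KeyError:
            raise ValueError(
                f"{role} marker {marker!r} absent in species "
                f"{table.species_id!r}"
            ) from None
        if v <= 0:
            raise ValueError(
                f"{role} marker {marker!r} has non-positive RPKM ({v}) in "
                f"species {table.species_id!r}"
            )
        values[role] = v
    return CompositionProfile(
        species_id=table.species_id,
        glia_marker=glia_marker.upper(),
        neuron_marker=neuron_marker.upper(),
        glia_rpkm=values["glia"],
        neuron_rpkm=values["neuron"],
    )


def composition_correct(
    target_rpkm: float, profile: CompositionProfile, mode: str = "divide"
) -> float:
    """Composition-correct a target gene's RPKM with the sample's ratio.

    ``divide`` (default) returns expression per glial unit, appropriate for a
    predominantly glial target; ``multiply`` is provided for the opposite
    convention.
    """
    if target_rpkm <= 0:
        raise ValueError(f"target RPKM must be positive, got {target_rpkm}")
    r = profile.ratio
    if mode == "divide":
        return target_rpkm / r
    if mode == "multiply":
        return target_rpkm * r
    raise ValueError(f"unknown correction mode {mode!r}")


def two_group_ttest(
    values_a, values_b, variant: str = "student_pooled"
) -> GroupComparison:
    """Two-tailed two-sample t-test on untransformed values.

    ``student_pooled`` is the classic equal-variance Student test; ``welch``
    does not pool.  Identical degenerate groups give t = 0, p = 1; zero
    pooled variance with unequal means raises (the statistic is infinite).
    """

    def _coerce(vals, label):
        pairs = []
        for v in vals:
            if isinstance(v, tuple):
                pairs.append((str(v[0]), float(v[1])))
            else:
                pairs.append(("", float(v)))
        x = np.array([p[1] for p in pairs], dtype=float)
        if len(x) < 2:
            raise ValueError(f"group {label} needs at least 2 values, got {len(x)}")
        if not np.isfinite(x).all():
            raise ValueError(f"group {label} contains non-finite values")
        return pairs, x

    pairs_a, xa = _coerce(values_a, "a")
    pairs_b, xb = _coerce(values_b, "b")
    na, nb = len(xa), len(xb)
    ma, mb = xa.mean(), xb.mean()
    va, vb = xa.var(ddof=1), xb.var(ddof=1)

    if variant == "student_pooled":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    elif variant == "welch":
        se = np.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")

    if se == 0:
        if ma == mb:
            t, p = 0.0, 1.0
        else:
            raise DegenerateVarianceError(
                "zero within-group variance with unequal group means"
            )
    else:
        t = (ma - mb) / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return GroupComparison(
        group_a=pairs_a,
        group_b=pairs_b,
        t_statistic=float(t),
        df=float(df),
        p_two_tailed=float(p),
    )


def read_groups_table(path) -> pd.DataFrame:
    """Species-group TSV: species_id, group, optional neuron_marker_override."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("species_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "neuron_marker_override" not in df.columns:
        df["neuron_marker_override"] = pd.NA
    return df.set_index("species_id")


def corrected_group_values(
    tables: list[ExpressionTable],
    target: str,
    groups: pd.DataFrame,
    glia_marker: str = DEFAULT_GLIA_MARKER,
    neuron_marker: str = DEFAULT_NEURON_MARKER,
    mode: str = "divide",
) -> pd.DataFrame:
    """Per-species marker ratios and corrected target values, joined to groups.

    ``groups`` is the frame from :func:`read_groups_table`; a per-species
    ``neuron_marker_override`` (e.g. SNAP25 for pig) replaces the default
    neuronal marker for that species only.
    """
    rows = []
    for t in tables:
        if t.species_id not in groups.index:
            raise ValueError(f"species {t.species_id!r} missing from groups table")
        override = groups.at[t.species_id, "neuron_marker_override"]
        nm = neuron_marker if pd.isna(override) else str(override)
        prof = glia_neuron_ratio(t, glia_marker=glia_marker, neuron_marker=nm)
        target_rpkm = t.rpkm_of(target)
        rows.append(
            {
                "species_id": t.species_id,
                "group": groups.at[t.species_id, "group"],
                "target_rpkm": target_rpkm,
                "glia_marker_rpkm": prof.glia_rpkm,
                "neuron_marker_rpkm": prof.neuron_rpkm,
                "ratio": prof.ratio,
                "corrected": composition_correct(target_rpkm, prof, mode=mode),
            }
        )
    return pd.DataFrame(rows).set_index("species_id")
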