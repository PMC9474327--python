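"""Multi-gene synthetic single-cell datasets with known ground truth.

Each gene is generated independently from the two-subset mixture generative
scheme (donor-level Normal/Uniform parameter draws, then per-cell mixture
draws), sharing the cell and sample indices across genes.  Gene archetypes
encode the canonical situations:

* ``null`` — no group difference;
* ``de`` — a bulk mean difference (expression shift with unchanged proportion);
* ``dv_proportion`` — equal means, variance changed through the subset
  proportion (the high-variance subset shrinks);
* ``dv_shift`` — equal means, variance changed through a widened
  component-mean gap;
* ``cancel`` — a positive subset-+ expression shift exactly offset by a
  proportion decrease, invisible to bulk DE analysis but visible to the
  per-sample decomposition.

Archetype labels are checked against the closed-form mean/variance group
differences at generation time, so a mislabeled archetype fails before any
sampling.  Values are continuous normal mixtures by default; an optional
truncation/count mode exists for I/O realism but perturbs the moments and is
not used in oracle comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import SingleCellDataset
from .model import (
    GroupParams,
    InvalidParameterError,
    MeasurementNoise,
    ShiftParams,
    apply_shift,
    cancellation_alpha_bound,
    mean_difference,
    variance_bulk,
)
from .simulate import SimulationConfig, sample_donor_params, simulate_cells

__all__ = ["GeneArchetype", "generate_dataset", "default_archetype_panel", "ARCHETYPE_LABELS"]

ARCHETYPE_LABELS = ("null", "de", "dv_proportion", "dv_shift", "cancel")

_LABEL_TOL = 1e-9


@dataclass(frozen=True)
class GeneArchetype:
    """One gene's generative parameters plus its expected behaviour label."""

    name: str
    group_params: GroupParams
    shift: ShiftParams
    v_y_plus: float = 1.0
    v_y_minus: float = 1.0
    label: str = "null"

    def __post_init__(self) -> None:
        if self.label not in ARCHETYPE_LABELS:
            raise InvalidParameterError(
                f"label must be one of {ARCHETYPE_LABELS}, got {self.label!r}"
            )
        if self.v_y_plus < 0 or self.v_y_minus < 0:
            raise InvalidParameterError("cell-level variances must be >= 0")
        self.validate_label()

    def deltas(self) -> tuple[float, float]:
        """Closed-form (mean difference, variance difference) between groups."""
        dmean = mean_difference(self.group_params, self.shift)
        no_noise = MeasurementNoise(0.0)
        dvar = variance_bulk(apply_shift(self.group_params, self.shift), no_noise) - variance_bulk(
            self.group_params, no_noise
        )
        return dmean, dvar

    def validate_label(self) -> None:
        dmean, dvar = self.deltas()
        label = self.label
        if label == "null":
            ok = abs(dmean) <= _LABEL_TOL and abs(dvar) <= _LABEL_TOL
        elif label == "de":
            ok = abs(dmean) > _LABEL_TOL
        elif label in ("dv_proportion", "dv_shift"):
            ok = abs(dmean) <= _LABEL_TOL and abs(dvar) > _LABEL_TOL
        else:  # cancel
            ok = abs(dmean) <= _LABEL_TOL and self.shift.d_plus > 0
        if not ok:
            raise InvalidParameterError(
                f"archetype {self.name!r} labelled {label!r} is inconsistent with its "
                f"closed-form deltas (mean {dmean:.6g}, variance {dvar:.6g})"
            )


def default_archetype_panel(n_null: int = 16) -> list[GeneArchetype]:
    """A 20-gene panel (with the default ``n_null``): nulls plus one gene of
    each non-null archetype, all at expression levels that pass the > 20
    grand-mean filter.

    The two DV archetypes transplant the canonical equal-mean constructions
    to a high expression baseline (component means 30/31); the ``cancel``
    gene uses a 10-unit component gap so the per-sample decomposition can
    resolve the subsets cleanly.
    """
    null_gp = GroupParams(e_plus=30.0, e_minus=22.0, e_r=0.5, v_plus=0.3, v_minus=0.1, v_r=0.01)
    no_shift = ShiftParams(0.0, 0.0, 1.0)
    panel = [
        GeneArchetype(f"null_{i + 1:02d}", null_gp, no_shift, label="null")
        for i in range(n_null)
    ]
    panel.append(
        GeneArchetype("de_gene", null_gp, ShiftParams(0.5, 0.5, 1.0), label="de")
    )
    gp_prop = GroupParams(e_plus=31.0, e_minus=30.0, e_r=0.9, v_plus=1.0, v_minus=0.1, v_r=0.001)
    panel.append(
        GeneArchetype(
            "dv_proportion_gene",
            gp_prop,
            ShiftParams(0.5, 0.5, cancellation_alpha_bound(gp_prop, 0.5, 0.5)),
            label="dv_proportion",
        )
    )
    gp_shift = GroupParams(e_plus=31.0, e_minus=30.0, e_r=0.9, v_plus=0.01, v_minus=0.01, v_r=0.001)
    panel.append(
        GeneArchetype(
            "dv_shift_gene",
            gp_shift,
            ShiftParams(10.0, 0.1, cancellation_alpha_bound(gp_shift, 10.0, 0.1)),
            label="dv_shift",
        )
    )
    gp_cancel = GroupParams(e_plus=35.0, e_minus=25.0, e_r=0.6, v_plus=0.3, v_minus=0.1, v_r=0.001)
    panel.append(
        GeneArchetype(
            "cancel_gene",
            gp_cancel,
            ShiftParams(0.3, 0.0, cancellation_alpha_bound(gp_cancel, 0.3, 0.0)),
            label="cancel",
        )
    )
    return panel


def generate_dataset(
    archetypes: list[GeneArchetype],
    samples_per_group: int,
    cells_per_sample: int,
    seed: int = 0,
    mode: str = "continuous",
) -> tuple[SingleCellDataset, pd.DataFrame]:
    """Assemble a cells x genes dataset gene-by-gene from independent draws.

    All genes share the sample layout (``samples_per_group`` donors per group,
    ``cells_per_sample`` cells each) but are generated from independent
    random streams, so inter-gene correlation is zero by construction.

    ``mode`` is ``"continuous"`` (raw normal-mixture values, may be
    negative), ``"truncate"`` (clipped at 0) or ``"counts"`` (rounded then
    clipped).  The returned ground-truth table has one row per (gene, sample)
    with the realised donor parameters, the archetype label, the closed-form
    group deltas and — in the non-continuous modes — the fraction of values
    the transformation altered.

    Raises
    ------
    InvalidParameterError
        If any archetype is invalid (checked before any sampling) or names
        collide.
    """
    if mode not in ("continuous", "truncate", "counts"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    names = [a.name for a in archetypes]
    if len(set(names)) != len(names):
        raise InvalidParameterError("duplicate archetype names")
    for arch in archetypes:
        arch.validate_label()

    n_genes = len(archetypes)
    n_samples_total = 2 * samples_per_group
    n_cells_total = n_samples_total * cells_per_sample

    sample_ids = [f"C{i + 1:04d}" for i in range(samples_per_group)] + [
        f"D{i + 1:04d}" for i in range(samples_per_group)
    ]
    sample_group = {s: s[0] for s in sample_ids}
    cell_ids = [f"{s}_cell{j + 1:05d}" for s in sample_ids for j in range(cells_per_sample)]
    cell_sample = np.repeat(np.asarray(sample_ids, dtype=object), cells_per_sample)

    matrix = np.empty((n_cells_total, n_genes))
    truth_rows = []
    gene_streams = np.random.SeedSequence(seed).spawn(n_genes)

    for g, (arch, gene_ss) in enumerate(zip(archetypes, gene_streams)):
        cfg = SimulationConfig(
            n_samples=samples_per_group,
            n_cells=cells_per_sample,
            v_y_plus=arch.v_y_plus,
            v_y_minus=arch.v_y_minus,
            seed=0,  # unused here; streams come from gene_ss
        )
        ss_c, ss_d, ss_cells = gene_ss.spawn(3)
        donors = sample_donor_params(
            arch.group_params, None, samples_per_group, np.random.default_rng(ss_c)
        )
        donors += sample_donor_params(
            arch.group_params, arch.shift, samples_per_group, np.random.default_rng(ss_d)
        )
        dmean, dvar = arch.deltas()
        cell_streams = ss_cells.spawn(len(donors))
        for s, (dp, stream) in enumerate(zip(donors, cell_streams)):
            cells = simulate_cells(dp, cfg, np.random.default_rng(stream))
            altered = 0.0
            if mode == "truncate":
                altered = float((cells < 0).mean())
                cells = np.clip(cells, 0.0, None)
            elif mode == "counts":
                rounded = np.clip(np.rint(cells), 0.0, None)
                altered = float((rounded != cells).mean())
                cells = rounded
            lo = s * cells_per_sample
            matrix[lo : lo + cells_per_sample, g] = cells
            truth_rows.append(
                {
                    "gene": arch.name,
                    "sample_id": sample_ids[s],
                    "group": dp.group,
                    "mu_plus": dp.mu_plus,
                    "mu_minus": dp.mu_minus,
                    "r": dp.r,
                    "archetype": arch.label,
                    "delta_mean_true": dmean,
                    "delta_var_true": dvar,
                    "altered_fraction": altered,
                }
            )

    dataset = SingleCellDataset(
        matrix=matrix,
        gene_ids=names,
        cell_ids=cell_ids,
        cell_sample=cell_sample,
        sample_group=sample_group,
    )
    return dataset, pd.DataFrame(truth_rows)
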