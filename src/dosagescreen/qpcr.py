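"""Relative qPCR quantification by the ddCt (Livak) method.

Per sample: Ct values are averaged over technical replicates, the target gene
is normalized to a reference gene (dCt = Ct_target - Ct_reference), centered
on the control group's mean dCt (ddCt), and expressed as fold-change
2^(-ddCt).  Centering on the arithmetic mean of control dCt makes the
geometric mean of control-group relative expression exactly 1.

Wells flagged not-detected propagate as explicit flags: a sample whose target
was not detected is reported not-detected, never as zero expression; a sample
whose *reference* was not detected is unusable and excluded with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CT_COLUMNS = ["gene", "sample", "group", "ct", "detected"]


def _mean_ct(sub: pd.DataFrame) -> tuple[float, bool]:
    """Technical-replicate mean Ct and a detected flag for one gene/sample."""
    det = sub[sub["detected"]]
    if det.empty:
        return float("nan"), False
    return float(det["ct"].mean()), True


def ddct_relative_expression(
    table: pd.DataFrame,
    target: str,
    reference: str,
    control_group: str,
) -> pd.DataFrame:
    """Per-sample relative expression of ``target`` normalized to ``reference``.

    ``table`` has one row per well: columns gene, sample, group, ct, detected.
    Returns a DataFrame indexed by sample with columns group, ct_target,
    ct_reference, delta_ct, delta_delta_ct, rel_expr, detected.
    """
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    det_ct = table.loc[table["detected"], "ct"]
    if not np.isfinite(det_ct).all() or (det_ct <= 0).any():
        raise ValueError("detected Ct values must be positive and finite")

    rows = []
    for sample, sub in table.groupby("sample", sort=True):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"sample {sample!r} assigned to multiple groups")
        ct_ref, ref_det = _mean_ct(sub[sub["gene"] == reference])
        ct_tgt, tgt_det = _mean_ct(sub[sub["gene"] == target])
        if not ref_det:
            logger.warning(
                "sample %r: reference gene %r not detected, sample excluded", sample, reference
            )
            continue
        rows.append(
            {
                "sample": sample,
                "group": groups[0],
                "ct_target": ct_tgt,
                "ct_reference": ct_ref,
                "delta_ct": ct_tgt - ct_ref,
                "detected": tgt_det,
            }
        )
    out = pd.DataFrame(rows).set_index("sample")
    ctrl = out[(out["group"] == control_group) & out["detected"]]
    if ctrl.empty:
        raise ValueError(f"no usable samples in control group {control_group!r}")
    ctrl_mean_dct = float(ctrl["delta_ct"].mean())
    out["delta_delta_ct"] = out["delta_ct"] - ctrl_mean_dct
    out["rel_expr"] = np.power(2.0, -out["delta_delta_ct"])
    # not-detected targets stay flagged, never 0
    out.loc[~out["detected"], ["delta_ct", "delta_delta_ct", "rel_expr"]] = np.nan
    return out
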