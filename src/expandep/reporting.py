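"""Tabular reports: gap/voltage tables and ablated-volume tables.

Reports are pandas DataFrames with deterministic CSV/JSON emitters, and
every JSON report carries an ``assumptions`` block naming the modelling
decisions in force (gap-formula reconstruction, rounding rule, the
conductivity-transition defaults) so downstream users can audit them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .geometry import gaps, round_half_up
from .planning import build_plan, Protocol
from .registry import ModelPreset, get_model
from .volumetrics import (
    EllipsoidMeasure,
    SegmentationVolume,
    diameters_from_mask,
    ellipsoid_volume,
    voxel_volume,
)

__all__ = ["assumptions", "gaps_table", "volume_report", "report_json"]


def assumptions() -> dict:
    """Modelling decisions surfaced in every JSON report."""
    return {
        "gap_formula": (
            "centre distance r = (e + h_t) tan(alpha) + i/2; gaps subtract one "
            "full needle diameter: d/2 = r - D, d = 2r - D, side = sqrt(2) r - D"
        ),
        "rounding": "half-up; gaps to 2 decimals, voltages to the model granularity",
        "conductivity_model": (
            "smoothstep from 0.1 to 0.3 S/m between 400 and 800 V/cm of the "
            "running maximum field magnitude (transition thresholds are "
            "modelling assumptions, configurable)"
        ),
        "outer_boundary": "insulating (zero normal current)",
        "voxel_count_spacing_note": (
            "the voxel-count estimator is surfaced both with the header pixel "
            "spacing and with any override, because reported pixel spacings "
            "are frequently rounded"
        ),
    }


def _resolve(model: Union[str, ModelPreset]) -> ModelPreset:
    return model if isinstance(model, ModelPreset) else get_model(model)


def gaps_table(
    models: Sequence[Union[str, ModelPreset]],
    deployments_mm: Sequence[float],
    protocol: Optional[Protocol] = None,
    include_voltages: bool = True,
) -> pd.DataFrame:
    """One row per (model, deployment) with rounded gaps and planned voltages.

    With ``protocol=None`` each model is planned against its own default
    regime and target field; a shared protocol overrides that.
    """
    records = []
    for model in models:
        preset = _resolve(model)
        spec = preset.spec
        for e in deployments_mm:
            g = gaps(spec, e)
            row: dict = {
                "model": preset.name,
                "deployment_mm": float(e),
                "side_mm": round_half_up(g.side_mm),
                "diagonal_mm": round_half_up(g.diagonal_mm),
                "semi_diagonal_mm": (
                    None
                    if g.semi_diagonal_mm is None
                    else round_half_up(g.semi_diagonal_mm)
                ),
            }
            if include_voltages:
                proto = protocol
                if proto is None:
                    if preset.default_regime == "reversible":
                        proto = Protocol.esope(preset.default_target_field_V_per_cm)
                    else:
                        proto = Protocol.ire(
                            preset.default_target_field_V_per_cm,
                            pulse_count=preset.default_pulse_count,
                        )
                (plan,) = build_plan(
                    spec, [e], proto, granularity_V=preset.voltage_granularity_V
                )
                classes = {entry.pair.pair_class for entry in plan.entries}
                row["V_side_V"] = plan.voltage("side")
                row["V_diagonal_V"] = (
                    plan.voltage("diagonal") if "diagonal" in classes else None
                )
                row["V_semi_diagonal_V"] = (
                    plan.voltage("semi_diagonal") if "semi_diagonal" in classes else None
                )
                row["target_field_V_per_cm"] = proto.target_field_V_per_cm
                row["pulses"] = plan.total_pulses
            records.append(row)
    columns = [
        "model",
        "deployment_mm",
        "side_mm",
        "diagonal_mm",
        "semi_diagonal_mm",
    ]
    if include_voltages:
        columns += [
            "V_side_V",
            "V_diagonal_V",
            "V_semi_diagonal_V",
            "target_field_V_per_cm",
            "pulses",
        ]
    return pd.DataFrame.from_records(records, columns=columns)


def volume_report(
    inputs: Sequence[tuple[str, Union[EllipsoidMeasure, SegmentationVolume]]],
    override_ps_mm: Optional[float] = None,
) -> pd.DataFrame:
    """Ablated-volume table mirroring both estimators.

    ``inputs`` pairs a label with either a diameter triple (ellipsoid
    estimator only) or a segmentation mask (both estimators).  With
    ``override_ps_mm`` the voxel-count estimator is additionally
    evaluated at that in-plane pixel spacing, surfacing the sensitivity
    of V_CT to rounded spacing metadata.
    """
    if not inputs:
        raise ConfigurationError("volume_report needs at least one input")
    records = []
    for label, item in inputs:
        row: dict = {"label": label}
        if isinstance(item, EllipsoidMeasure):
            measure = item
            row.update(n_pixel=None, V_CT_cm3=None, V_CT_override_cm3=None)
        elif isinstance(item, SegmentationVolume):
            measure = diameters_from_mask(item)
            row["n_pixel"] = item.n_pixel
            row["V_CT_cm3"] = round_half_up(voxel_volume(item), 2)
            if override_ps_mm is not None:
                scaled = SegmentationVolume(
                    mask=item.mask,
                    ps_o_mm=override_ps_mm,
                    ps_v_mm=override_ps_mm,
                    st_mm=item.st_mm,
                    sbs_mm=item.sbs_mm,
                )
                row["V_CT_override_cm3"] = round_half_up(voxel_volume(scaled), 2)
            else:
                row["V_CT_override_cm3"] = None
        else:
            raise ConfigurationError(
                f"unsupported volume input for {label!r}: {type(item).__name__}"
            )
        d = measure.diameters_cm
        row["diameter_a_cm"] = d[0]
        row["diameter_b_cm"] = d[1]
        row["diameter_c_cm"] = d[2]
        row["V_ellipsoid_cm3"] = round_half_up(ellipsoid_volume(measure), 2)
        records.append(row)
    columns = [
        "label",
        "diameter_a_cm",
        "diameter_b_cm",
        "diameter_c_cm",
        "V_ellipsoid_cm3",
        "n_pixel",
        "V_CT_cm3",
        "V_CT_override_cm3",
    ]
    return pd.DataFrame.from_records(records, columns=columns)


def report_json(payload: dict, out: Optional[Union[str, Path]] = None) -> str:
    """Serialize a report deterministically (sorted keys, fixed layout)."""
    doc = {
        "tool": "expandep",
        "version": __version__,
        "assumptions": assumptions(),
        **payload,
    }
    text = json.dumps(doc, indent=2, sort_keys=True, default=_jsonify) + "\n"
    if out is not None:
        Path(out).write_text(text)
    return text


def _jsonify(obj):
    try:
        import numpy as np

        if isinstance(obj, np.generic):
            return obj.item()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")
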