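"""TSV/JSON report writers shared by the CLI stages.

All writers produce a header row, a stable column order and fixed
float formatting, so re-running a stage on identical input yields
byte-identical files.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .annotate import AnnotatedGlycan
from .calibrate import CalibrationModel, is_extrapolation
from .ladder import LadderAssignment, LadderObservation
from .quantify import CompositionQuant


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def write_ladder_tsv(
    observations: list[LadderObservation], assignment: LadderAssignment, path: str
) -> None:
    rows = [
        {
            "gu": o.gu,
            "rt": o.rt,
            "intensity": o.intensity,
            "scan_id": o.scan_id,
            "charge": o.charge,
            "assigned": int(assignment.rt_by_gu.get(o.gu) == o.rt),
        }
        for o in observations
    ]
    _write_tsv(pd.DataFrame(rows, columns=["gu", "rt", "intensity", "scan_id", "charge", "assigned"]), path)


def write_calibration_json(model: CalibrationModel, path: str) -> None:
    payload = {
        "kind": model.kind,
        "order": model.order,
        "coefficients": [float(c) for c in model.coefficients],
        "r_squared": model.r_squared,
        "fit_points": [[rt, gu] for rt, gu in model.fit_points],
        "center": model._center,
        "scale": model._scale,
        "scaled_coefficients": [float(c) for c in model._scaled_coefficients],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_calibration_json(path: str) -> CalibrationModel:
    with open(path) as fh:
        d = json.load(fh)
    return CalibrationModel(
        kind=d["kind"],
        order=d["order"],
        coefficients=np.array(d["coefficients"]),
        r_squared=d["r_squared"],
        fit_points=tuple((rt, gu) for rt, gu in d["fit_points"]),
        _center=d["center"],
        _scale=d["scale"],
        _scaled_coefficients=np.array(d["scaled_coefficients"]),
    )


def write_calibration_tsv(model: CalibrationModel, path: str) -> None:
    from .calibrate import rt_to_gui

    rows = [
        {"rt": rt, "gu": gu, "fitted_gui": float(rt_to_gui(model, rt))}
        for rt, gu in model.fit_points
    ]
    _write_tsv(pd.DataFrame(rows, columns=["rt", "gu", "fitted_gui"]), path)


def write_annotations_tsv(
    annotations: list[AnnotatedGlycan], model: CalibrationModel, path: str
) -> None:
    rows = [
        {
            "composition": str(a.composition),
            "charge": a.charge,
            "adduct": a.adduct,
            "scan_id": a.scan_id,
            "rt": a.rt,
            "gui": a.gui,
            "score": a.score,
            "anchor_mz": a.matched_mz,
            "extrapolated": int(is_extrapolation(model, a.rt)),
        }
        for a in annotations
    ]
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=["composition", "charge", "adduct", "scan_id", "rt", "gui", "score", "anchor_mz", "extrapolated"],
        ),
        path,
    )


def read_annotations_tsv(path: str) -> list[AnnotatedGlycan]:
    from .compositions import GlycanComposition

    df = pd.read_csv(path, sep="\t")
    return [
        AnnotatedGlycan(
            composition=GlycanComposition.from_string(r.composition),
            charge=int(r.charge),
            adduct=r.adduct,
            scan_id=r.scan_id,
            rt=float(r.rt),
            score=float(r.score),
            gui=float(r.gui),
            matched_mz=float(r.anchor_mz),
        )
        for r in df.itertuples()
    ]


def write_quantification_tsv(quants: list[CompositionQuant], path: str) -> None:
    rows = []
    for q in quants:
        for i, p in enumerate(q.isomers, start=1):
            rows.append(
                {
                    "composition": str(q.composition),
                    "isomer": i,
                    "apex_rt": p.apex_rt,
                    "gui": p.gui,
                    "left_rt": p.left_rt,
                    "right_rt": p.right_rt,
                    "area": p.area,
                    "total_area": q.total_area,
                }
            )
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=["composition", "isomer", "apex_rt", "gui", "left_rt", "right_rt", "area", "total_area"],
        ),
        path,
    )


def write_summary_json(summary: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
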