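"""Tabular model dialect: an XLSX workbook (sheets ``reactions``,
``metabolites``, ``genes``, ``model``) or an equivalent CSV quadruplet in a
directory. Reaction equations use the arrow dialect ``a A + b B → c C``
(``⇌`` for reversible; ASCII ``->`` / ``<=>`` accepted); explicit bound
columns take precedence over the arrow, which only sets defaults.
Annotation maps are JSON-encoded in an ``annotations`` column.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from ..gpr import parse_gpr
from ..model import Gene, MetabolicModel, Metabolite, Reaction

__all__ = ["read_tabular_model", "write_tabular_model", "TabularError"]

_SHEETS = ("reactions", "metabolites", "genes", "model")
_REVERSIBLE_ARROWS = ("⇌", "<=>", "<->")
_IRREVERSIBLE_ARROWS = ("→", "->")


class TabularError(ValueError):
    """Malformed tabular model input."""


def _fmt_coeff(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else repr(float(c))


def format_equation(rxn: Reaction) -> str:
    subs = [(m, -c) for m, c in rxn.stoichiometry.items() if c < 0]
    prods = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]

    def side(terms: List[Tuple[str, float]]) -> str:
        return " + ".join(
            m if c == 1 else f"{_fmt_coeff(c)} {m}" for m, c in terms
        )

    arrow = "⇌" if rxn.lower_bound < 0 else "→"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


def parse_equation(text: str, row_label: str = "") -> Tuple[Dict[str, float], bool]:
    """Parse an equation string into (stoichiometry, reversible)."""
    arrow = None
    reversible = False
    for a in _REVERSIBLE_ARROWS:
        if a in text:
            arrow, reversible = a, True
            break
    if arrow is None:
        for a in _IRREVERSIBLE_ARROWS:
            if a in text:
                arrow = a
                break
    if arrow is None:
        raise TabularError(f"row {row_label}: no reaction arrow in {text!r}")
    left, right = text.split(arrow, 1)
    stoich: Dict[str, float] = {}

    def consume(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                mid, coeff = parts[0], 1.0
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError as exc:
                    raise TabularError(
                        f"row {row_label}: bad coefficient in {term!r}"
                    ) from exc
                mid = parts[1]
            else:
                raise TabularError(f"row {row_label}: cannot parse term {term!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff

    consume(left, -1.0)
    consume(right, +1.0)
    return stoich, reversible


def _annotations_json(ann: Dict[str, str]) -> str:
    return json.dumps(ann, sort_keys=True) if ann else ""


def _parse_annotations(val) -> Dict[str, str]:
    if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
        return {}
    return json.loads(val)


def _frames(model: MetabolicModel) -> Dict[str, pd.DataFrame]:
    rxn_rows = [
        {
            "id": r.id,
            "name": r.name,
            "equation": format_equation(r),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "gpr": r.gpr.to_string(),
            "subsystem": r.subsystem,
            "annotations": _annotations_json(r.annotations),
        }
        for r in model.reactions.values()
    ]
    met_rows = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "formula": m.formula or "",
            "charge": "" if m.charge is None else m.charge,
            "annotations": _annotations_json(m.annotations),
        }
        for m in model.metabolites.values()
    ]
    gene_rows = [
        {
            "id": g.id,
            "name": g.name,
            "genome_start": "" if g.genome_start is None else g.genome_start,
            "protein_length": "" if g.protein_length is None else g.protein_length,
            "protein_mass": "" if g.protein_mass is None else g.protein_mass,
            "protein_sequence": g.protein_sequence or "",
            "annotations": _annotations_json(g.annotations),
        }
        for g in model.genes.values()
    ]
    model_rows = [
        {
            "id": model.id,
            "objective_id": model.objective_id or "",
            "atp_maintenance_id": model.atp_maintenance_id or "",
        }
    ]
    columns = {
        "reactions": ["id", "name", "equation", "lower_bound", "upper_bound",
                      "gpr", "subsystem", "annotations"],
        "metabolites": ["id", "name", "compartment", "formula", "charge",
                        "annotations"],
        "genes": ["id", "name", "genome_start", "protein_length",
                  "protein_mass", "protein_sequence", "annotations"],
        "model": ["id", "objective_id", "atp_maintenance_id"],
    }
    rows = {"reactions": rxn_rows, "metabolites": met_rows,
            "genes": gene_rows, "model": model_rows}
    return {
        sheet: pd.DataFrame(rows[sheet], columns=columns[sheet])
        for sheet in columns
    }


def write_tabular_model(model: MetabolicModel, path: str) -> None:
    """Write a model as XLSX (``.xlsx`` suffix) or a CSV set in a directory."""
    frames = _frames(model)
    p = Path(path)
    if p.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(p) as xl:
            for sheet, frame in frames.items():
                frame.to_excel(xl, sheet_name=sheet, index=False)
    else:
        p.mkdir(parents=True, exist_ok=True)
        for sheet, frame in frames.items():
            frame.to_csv(p / f"{sheet}.csv", index=False)


def _opt_str(val) -> str:
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return ""
    return str(val)


def _opt_int(val) -> Optional[int]:
    s = _opt_str(val)
    return int(float(s)) if s else None


def _opt_float(val) -> Optional[float]:
    s = _opt_str(val)
    return float(s) if s else None


def read_tabular_model(path: str) -> MetabolicModel:
    """Read a model from the tabular dialect (XLSX or CSV directory)."""
    p = Path(path)
    frames: Dict[str, pd.DataFrame] = {}
    if p.is_file():
        book = pd.read_excel(p, sheet_name=None)
        lower = {name.lower(): frame for name, frame in book.items()}
        frames = {s: lower[s] for s in _SHEETS if s in lower}
    elif p.is_dir():
        for sheet in _SHEETS:
            f = p / f"{sheet}.csv"
            if f.exists():
                frames[sheet] = pd.read_csv(f, comment="#")
    else:
        raise TabularError(f"{path!r} is neither an XLSX file nor a directory")
    for sheet in ("reactions", "metabolites"):
        if sheet not in frames:
            raise TabularError(f"missing sheet/file {sheet!r} in {path!r}")

    meta = frames.get("model")
    model = MetabolicModel(
        id=_opt_str(meta.iloc[0]["id"]) if meta is not None and len(meta) else "model"
    )

    for _, row in frames["metabolites"].iterrows():
        model.add_metabolite(
            Metabolite(
                id=str(row["id"]),
                name=_opt_str(row.get("name")),
                compartment=_opt_str(row.get("compartment")) or "c",
                formula=_opt_str(row.get("formula")) or None,
                charge=_opt_int(row.get("charge")),
                annotations=_parse_annotations(row.get("annotations")),
            )
        )

    if "genes" in frames:
        for _, row in frames["genes"].iterrows():
            model.add_gene(
                Gene(
                    id=str(row["id"]),
                    name=_opt_str(row.get("name")),
                    genome_start=_opt_int(row.get("genome_start")),
                    protein_length=_opt_int(row.get("protein_length")),
                    protein_mass=_opt_float(row.get("protein_mass")),
                    protein_sequence=_opt_str(row.get("protein_sequence")) or None,
                    annotations=_parse_annotations(row.get("annotations")),
                )
            )

    for _, row in frames["reactions"].iterrows():
        rid = str(row["id"])
        stoich, reversible = parse_equation(str(row["equation"]), row_label=rid)
        for mid in stoich:
            if mid not in model.metabolites:
                raise TabularError(
                    f"row {rid!r}: equation references undeclared metabolite {mid!r}"
                )
        lb = _opt_float(row.get("lower_bound"))
        ub = _opt_float(row.get("upper_bound"))
        if lb is None:
            lb = -1000.0 if reversible else 0.0
        if ub is None:
            ub = 1000.0
        model.add_reaction(
            Reaction(
                id=rid,
                name=_opt_str(row.get("name")),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(_opt_str(row.get("gpr"))),
                subsystem=_opt_str(row.get("subsystem")),
                annotations=_parse_annotations(row.get("annotations")),
            )
        )

    if meta is not None and len(meta):
        obj = _opt_str(meta.iloc[0].get("objective_id"))
        maint = _opt_str(meta.iloc[0].get("atp_maintenance_id"))
        model.objective_id = obj or None
        model.atp_maintenance_id = maint or None
    return model
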