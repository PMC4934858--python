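"""Metabolic model input/output and gene–protein–reaction (GPR) utilities.

Models are held as :class:`cobra.Model` objects and read/written through
COBRApy in either SBML (Level 3 + FBC) or BiGG-style JSON.  On top of the
plain container this module provides the two GPR-derived quantities the
dynamic-expression method needs:

* the *enzyme-set signature* of a reaction — the set of all gene ids in its
  GPR, used to lump reactions that are catalyzed by the same enzymes;
* the *apparent gene length* of a multi-copy subunit — the coding length
  plus one interribosomal spacing per copy, which sets the effective
  translation time of a homo-multimeric complex.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import cobra
from cobra.util.solver import linear_reaction_coefficients

logger = logging.getLogger(__name__)

#: Average distance between consecutive ribosomes on an mRNA (bp).
DEFAULT_RIBOSOME_SPACING_BP = 72

_BIGG_REACTION_FIELDS = {
    "id", "name", "metabolites", "lower_bound", "upper_bound",
    "gene_reaction_rule", "objective_coefficient", "subsystem",
    "notes", "annotation",
}


class ModelParseError(ValueError):
    """Raised when a model file is malformed (names the offending element)."""


class ModelConfigurationError(ValueError):
    """Raised when a parsed model violates a structural requirement."""


def _detect_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower().replace("_", "-")
        if fmt not in {"sbml", "bigg-json", "json"}:
            raise ValueError(f"unknown model format {fmt!r}")
        return "bigg-json" if fmt == "json" else fmt
    suffix = Path(path).suffix.lower()
    if suffix in {".xml", ".sbml"}:
        return "sbml"
    if suffix == ".json":
        return "bigg-json"
    raise ValueError(f"cannot infer model format from {path!r}; pass format=")


def _prevalidate_bigg_json(path: Path) -> None:
    """Schema check on the raw JSON so errors can name the bad element."""
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("reactions", "metabolites"):
        if key not in doc:
            raise ModelParseError(f"{path}: missing top-level '{key}' array")
    declared = {m.get("id") for m in doc["metabolites"]}
    for rxn in doc["reactions"]:
        rid = rxn.get("id", "<no id>")
        unknown = set(rxn) - _BIGG_REACTION_FIELDS
        if unknown:
            logger.warning("reaction %s: ignoring unknown fields %s", rid, sorted(unknown))
        for met in rxn.get("metabolites", {}):
            if met not in declared:
                raise ModelParseError(
                    f"{path}: reaction '{rid}' references undeclared metabolite '{met}'"
                )
        lb, ub = rxn.get("lower_bound", 0.0), rxn.get("upper_bound", 0.0)
        if lb > ub:
            raise ModelParseError(
                f"{path}: reaction '{rid}' has lower_bound {lb} > upper_bound {ub}"
            )


def validate_model(model: cobra.Model) -> None:
    """Check the structural invariants required downstream.

    Raises :class:`ModelConfigurationError` on: missing/ambiguous objective,
    or inverted bounds.  Exchange reactions are not required but their
    detection is exercised so a malformed boundary shows up early.
    """
    objectives = linear_reaction_coefficients(model)
    if len(objectives) != 1:
        raise ModelConfigurationError(
            f"model '{model.id}' must have exactly one objective reaction, "
            f"found {len(objectives)}"
        )
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelConfigurationError(
                f"reaction '{rxn.id}': lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )


def read_model(path: str | Path, format: str | None = None) -> cobra.Model:
    """Read a metabolic model from SBML or BiGG-style JSON.

    Parameters
    ----------
    path:
        Model file.  ``.xml``/``.sbml`` are read as SBML, ``.json`` as
        BiGG JSON; pass ``format`` to override.
    format:
        ``"sbml"`` or ``"bigg-json"`` (alias ``"json"``).

    Returns
    -------
    cobra.Model
        Validated model with exactly one objective reaction.  Exchange
        reactions (single-metabolite boundary reactions, negative flux =
        uptake) are available via ``model.exchanges``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "bigg-json":
        _prevalidate_bigg_json(path)
        try:
            model = cobra.io.load_json_model(str(path))
        except Exception as exc:  # pragma: no cover - prevalidation catches most
            raise ModelParseError(f"{path}: {exc}") from exc
    else:
        try:
            model = cobra.io.read_sbml_model(str(path))
        except Exception as exc:
            raise ModelParseError(f"{path}: {exc}") from exc
    validate_model(model)
    return model


def write_model(model: cobra.Model, path: str | Path, format: str | None = None) -> None:
    """Write a model to SBML or BiGG-style JSON (inferred from suffix)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "bigg-json":
        cobra.io.save_json_model(model, str(path))
    else:
        cobra.io.write_sbml_model(model, str(path))


# ---------------------------------------------------------------------------
# Enzyme-set signatures


def enzyme_set(reaction_or_rule: cobra.Reaction | str) -> frozenset[str]:
    """Canonical gene-set signature of a reaction's GPR.

    Two reactions share a signature exactly when their GPRs mention the
    same genes, regardless of the Boolean tree shape (``"a and b"`` and
    ``"b and a"``, but also ``"a or b"``, are identical signatures — the
    signature deliberately ignores subunit vs. isoenzyme structure).
    An empty GPR yields the empty signature.
    """
    if isinstance(reaction_or_rule, cobra.Reaction):
        return frozenset(g.id for g in reaction_or_rule.genes)
    gpr = cobra.core.gene.GPR.from_string(reaction_or_rule)
    return frozenset(gpr.genes)


def enzyme_set_partition(model: cobra.Model,
                         reactions: Iterable[str] | None = None,
                         ) -> dict[frozenset[str], list[str]]:
    """Group reaction ids by enzyme-set signature.

    Reactions with an empty GPR are excluded: a reaction without gene
    association is never lumped with gene-bearing reactions (nor with other
    orphans, whose shared empty signature is not evidence of shared enzymes).
    """
    groups: dict[frozenset[str], list[str]] = {}
    if reactions is None:
        rxns = list(model.reactions)
    else:
        rxns = [model.reactions.get_by_id(r) for r in reactions]
    for rxn in rxns:
        sig = enzyme_set(rxn)
        if not sig:
            continue
        groups.setdefault(sig, []).append(rxn.id)
    return groups


# ---------------------------------------------------------------------------
# Gene lengths


def apparent_gene_length(length: int, copies: int = 1,
                         spacing: int = DEFAULT_RIBOSOME_SPACING_BP,
                         add_single: bool = False) -> int:
    """Effective gene length (bp) for translation of a homo-multimer.

    When an enzyme complex contains ``copies`` > 1 copies of its largest
    subunit, successive ribosomes translating those copies trail each other
    by roughly one interribosomal spacing, so the effective template length
    is ``length + copies * spacing``.  For a single copy the raw coding
    length is used unless ``add_single`` is set (in which case the spacing
    term is added for any copy number).

    Example: a 2802 bp subunit present in 12 copies with 72 bp spacing has
    an apparent length of 2802 + 12*72 = 3666 bp.
    """
    if length < 1:
        raise ValueError(f"gene length must be >= 1 bp, got {length}")
    if copies < 1:
        raise ValueError(f"copy number must be >= 1, got {copies}")
    if spacing < 0:
        raise ValueError(f"spacing must be >= 0 bp, got {spacing}")
    if copies > 1 or add_single:
        return length + copies * spacing
    return length


def largest_subunit(gene_lengths: Mapping[str, int]) -> str:
    """Gene id with maximal raw coding length; ties break lexicographically.

    The longest gene takes the longest to transcribe and translate and is
    therefore taken as rate-limiting for expression of the holoenzyme.
    """
    if not gene_lengths:
        raise ValueError("empty gene-length mapping")
    return min(gene_lengths, key=lambda g: (-gene_lengths[g], g))


def read_gene_info(path: str | Path):
    """Read a gene-info table (TSV: gene_id, length_bp, copies)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "length_bp"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: gene info table needs columns {sorted(required)}")
    if "copies" not in df.columns:
        df["copies"] = 1
    if (df["length_bp"] < 1).any() or (df["copies"] < 1).any():
        raise ValueError(f"{path}: gene lengths and copy numbers must be positive")
    return df
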