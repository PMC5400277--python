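"""The gynoecium medial-domain regulatory circuit and its knockout panel.

In the young Arabidopsis gynoecium, the bHLH transcription factor SPT
enables cytokinin (CK) signaling in the medial domain by activating
type-B response-regulator genes (ARR1, and likely ARR12).  The ARR1
protein becomes active only upon phosphorylation, which requires the
CK-initiated phosphorelay; SPT and phosphorylated ARR1 then jointly
(AND-gate, "cooperative regulation") activate auxin biosynthesis (TAA1)
and auxin efflux transport (PIN3), and TAA1 produces auxin (AUX).  In
the lateral domain the phosphorelay is interrupted by the repressors
AHP6 and (perhaps) ARR16.

This module encodes that circuit as a synchronous Boolean network in
three variants and reproduces the in silico experiments run on it:

* ``core_medial`` — the 7-node medial circuit (default).
* ``extended_medial`` — adds ARR12 as an SPT-activated sink node.
* ``lateral`` — adds AHP6/ARR16 repression of the CK signal via an
  explicit CKSIG node (``CKSIG = CK AND NOT (AHP6 OR ARR16)``).

ARR1 is split into a transcript node (``ARR1``, activated by SPT) and an
active-protein node (``ARR1P = ARR1 AND CK``) because transcriptional
activation and phosphorylation are separate control points; motif
analysis collapses the pair back to one gene (see
:mod:`gynogrn.motifs`).  CK and SPT are self-sustaining inputs whose
levels are set by clamping.  AUX is a produced species (``AUX = TAA1``);
PIN3 models transport capacity, not auxin consumption — the Boolean
layer cannot represent flux, so "auxin drainage" is interpretation, not
dynamics.  ARR10 and the hypothetical SPT links to further CK-signaling
components are recorded as metadata only, not instantiated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .engine import (
    And,
    Attractor,
    Const,
    NetworkModel,
    Not,
    Or,
    Var,
    clamp,
    enumerate_attractors,
)

__all__ = [
    "VARIANTS",
    "PERTURBATION_PANEL",
    "UnstableModelError",
    "PerturbationResult",
    "build_network",
    "wildtype_steady_state",
    "run_perturbation_panel",
]

VARIANTS = ("core_medial", "extended_medial", "lateral")

#: The four in silico knockouts, in canonical order: the transcription
#: factor, the hormone signal, the transporter, the biosynthesis enzyme.
PERTURBATION_PANEL = (("SPT", 0), ("CK", 0), ("PIN3", 0), ("TAA1", 0))


class UnstableModelError(RuntimeError):
    """The clamped model has more than one attractor (no unique steady
    state) — this would falsify the single-steady-state encoding."""


def build_network(variant: str = "core_medial", *,
                  include_arr12: bool | None = None,
                  ahp6_source: str = "input") -> NetworkModel:
    """Build a packaged model variant.

    Parameters
    ----------
    variant:
        ``core_medial``, ``extended_medial`` or ``lateral``.
    include_arr12:
        Convenience flag: ``build_network("core_medial",
        include_arr12=True)`` is the extended variant.
    ahp6_source:
        Lateral variant only.  ``"input"`` (default) makes AHP6 a
        self-sustaining input; ``"auxin"`` wires ``AHP6 = AUX``,
        the hypothesised auxin-activated source of the repressor.
    """
    if include_arr12:
        if variant == "core_medial":
            variant = "extended_medial"
        elif variant != "extended_medial":
            raise ValueError("include_arr12 only applies to the medial "
                             "variants")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of "
                         f"{VARIANTS}")
    if ahp6_source not in ("input", "auxin"):
        raise ValueError(f"unknown ahp6_source {ahp6_source!r}")
    if ahp6_source == "auxin" and variant != "lateral":
        raise ValueError("ahp6_source is an option of the lateral variant")

    metadata = {
        "variant": variant,
        "aliases": {"ARR1P": "ARR1"},
        "notes": (
            "ARR10 and hypothetical SPT links to additional cytokinin-"
            "signaling components are not instantiated as nodes/edges; "
            "TAA1 has further positive regulators omitted for parsimony."
        ),
    }

    if variant in ("core_medial", "extended_medial"):
        nodes = ["CK", "SPT", "ARR1", "ARR1P", "TAA1", "PIN3", "AUX"]
        rules = {
            "CK": Var("CK"),
            "SPT": Var("SPT"),
            "ARR1": Var("SPT"),
            "ARR1P": And(Var("ARR1"), Var("CK")),
            "TAA1": And(Var("SPT"), Var("ARR1P")),
            "PIN3": And(Var("SPT"), Var("ARR1P")),
            "AUX": Var("TAA1"),
        }
        if variant == "extended_medial":
            nodes.append("ARR12")
            rules["ARR12"] = Var("SPT")
        return NetworkModel(nodes, rules, metadata)

    # lateral: the CK literal of ARR1P is replaced by the gated signal
    metadata["ahp6_source"] = ahp6_source
    nodes = ["CK", "SPT", "AHP6", "ARR16", "CKSIG",
             "ARR1", "ARR1P", "TAA1", "PIN3", "AUX"]
    rules = {
        "CK": Var("CK"),
        "SPT": Var("SPT"),
        "AHP6": Var("AHP6") if ahp6_source == "input" else Var("AUX"),
        "ARR16": Var("ARR16"),
        "CKSIG": And(Var("CK"), Not(Or(Var("AHP6"), Var("ARR16")))),
        "ARR1": Var("SPT"),
        "ARR1P": And(Var("ARR1"), Var("CKSIG")),
        "TAA1": And(Var("SPT"), Var("ARR1P")),
        "PIN3": And(Var("SPT"), Var("ARR1P")),
        "AUX": Var("TAA1"),
    }
    return NetworkModel(nodes, rules, metadata)


def _clamp_inputs(model: NetworkModel, ck: int, spt: int,
                  extra_inputs: Mapping[str, int] | None = None
                  ) -> NetworkModel:
    clamped = clamp(clamp(model, "CK", ck), "SPT", spt)
    extra = dict(extra_inputs or {})
    for name in model.inputs:
        if name in ("CK", "SPT"):
            continue
        clamped = clamp(clamped, name, extra.pop(name, 0))
    if extra:
        raise ValueError(f"not input nodes of this variant: {sorted(extra)}")
    return clamped


def wildtype_steady_state(variant: str = "core_medial", ck: int = 1,
                          spt: int = 1, *,
                          extra_inputs: Mapping[str, int] | None = None,
                          **build_options) -> Attractor:
    """The unique attractor with the inputs clamped to ``(ck, spt)``.

    All declared inputs are clamped (further inputs of the lateral
    variant default to 0 unless given in ``extra_inputs``), attractors
    of the remaining free subspace are enumerated exhaustively, and the
    unique attractor is returned.  More than one attractor raises
    :class:`UnstableModelError`; for the medial variants a cyclic
    attractor also raises (the circuit is built to settle to a fixed
    steady expression state).
    """
    model = build_network(variant, **build_options)
    clamped = _clamp_inputs(model, ck, spt, extra_inputs)
    attractors = enumerate_attractors(clamped)
    if len(attractors) != 1:
        raise UnstableModelError(
            f"{variant} with CK={ck}, SPT={spt} has {len(attractors)} "
            f"attractors; expected a single steady state")
    att = attractors[0]
    if variant in ("core_medial", "extended_medial") and not att.is_fixed_point:
        raise UnstableModelError(
            f"{variant} with CK={ck}, SPT={spt} settles into a length-"
            f"{len(att)} cycle, not a fixed point")
    return att


@dataclass(frozen=True)
class PerturbationResult:
    """One in silico knockout against the wild-type steady state.

    ``changed_nodes`` holds every node whose steady value differs from
    wild type (the clamped node included, unless it already carried the
    clamped value); ``altered`` is true iff that set is non-empty.
    """

    node: str
    value: int
    attractor: Attractor
    changed_nodes: frozenset
    altered: bool

    @property
    def steady_state(self):
        return self.attractor.representative


def run_perturbation_panel(variant: str = "core_medial", **build_options
                           ) -> list:
    """Run the four knockouts {SPT<-0, CK<-0, PIN3<-0, TAA1<-0}.

    Each knockout is applied on top of the wild-type input condition
    (CK=1, SPT=1) by clamping the node to 0, and the resulting steady
    state is compared node-by-node with the wild-type steady state.
    For the core circuit every knockout alters the steady state — the
    model's prediction that development is disturbed in each mutant.
    """
    model = build_network(variant, **build_options)
    wt = wildtype_steady_state(variant, 1, 1, **build_options)
    wt_state = wt.representative
    results = []
    for node, value in PERTURBATION_PANEL:
        clamped = clamp(_clamp_inputs(model, 1, 1), node, value)
        attractors = enumerate_attractors(clamped)
        if len(attractors) != 1:
            raise UnstableModelError(
                f"{node}<-{value} on {variant} yields "
                f"{len(attractors)} attractors")
        att = attractors[0]
        changed = frozenset(
            name for name, a, b in zip(model.nodes, wt_state,
                                       att.representative)
            if a != b)
        results.append(PerturbationResult(
            node=node, value=value, attractor=att,
            changed_nodes=changed, altered=bool(changed)))
    return results
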