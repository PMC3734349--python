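"""Candidate network architectures for the attention network.

All models share the same 4-region intrinsic structure: reciprocal
VC<->SPL coupling within each hemisphere and no interhemispheric links.
They differ in where the attention input enters (SPL, VC, or both) and
which VC<->SPL directions it modulates (both, top-down only, bottom-up
only, or none), lateralized to one hemisphere.

The neurofeedback pair is ``attention_pair()``: M_aL drives and
modulates the *right* hemisphere (engaged by attending left), M_aR the
left.  ``model_family()`` builds the 12-model grid (3 input families x 4
modulation patterns) used for post-hoc architecture comparison; model 1
is the neurofeedback architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .data import CANONICAL_REGIONS
from .forward import ConnectivityParams

__all__ = [
    "ModelSpec",
    "DcmSkeleton",
    "attention_pair",
    "model_family",
    "mirror",
    "validate",
    "build_params",
]

_HEMI = {"left": "L", "right": "R"}
_INPUT_FAMILIES = ("SPL", "VC", "both")
_MODULATIONS = ("both", "top_down", "bottom_up", "none")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one candidate architecture.

    ``hemisphere`` names the side carrying the attention input and
    modulation.  ``input_targets`` / ``modulated_edges`` can be given
    explicitly; by default they are derived from ``input_family``,
    ``modulation`` and ``hemisphere``.
    """

    name: str
    input_family: str = "SPL"  # "SPL" | "VC" | "both"
    modulation: str = "both"   # "both" | "top_down" | "bottom_up" | "none"
    hemisphere: str = "right"  # side receiving input/modulation
    input_targets: tuple[str, ...] | None = None
    modulated_edges: tuple[tuple[str, str], ...] | None = None  # (src, dst)

    def resolved_input_targets(self) -> tuple[str, ...]:
        if self.input_targets is not None:
            return tuple(self.input_targets)
        side = _HEMI[self.hemisphere]
        fam = {"SPL": (f"SPL_{side}",), "VC": (f"VC_{side}",),
               "both": (f"SPL_{side}", f"VC_{side}")}
        return fam[self.input_family]

    def resolved_modulated_edges(self) -> tuple[tuple[str, str], ...]:
        if self.modulated_edges is not None:
            return tuple(tuple(e) for e in self.modulated_edges)
        side = _HEMI[self.hemisphere]
        top_down = (f"SPL_{side}", f"VC_{side}")
        bottom_up = (f"VC_{side}", f"SPL_{side}")
        return {
            "both": (top_down, bottom_up),
            "top_down": (top_down,),
            "bottom_up": (bottom_up,),
            "none": (),
        }[self.modulation]

    # -- YAML round-trip ----------------------------------------------------
    def to_yaml(self) -> str:
        d = {
            "name": self.name,
            "input_family": self.input_family,
            "modulation": self.modulation,
            "hemisphere": self.hemisphere,
        }
        if self.input_targets is not None:
            d["input_targets"] = list(self.input_targets)
        if self.modulated_edges is not None:
            d["modulated_edges"] = [list(e) for e in self.modulated_edges]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        d = yaml.safe_load(text)
        if d.get("input_targets") is not None:
            d["input_targets"] = tuple(d["input_targets"])
        if d.get("modulated_edges") is not None:
            d["modulated_edges"] = tuple(tuple(e) for e in d["modulated_edges"])
        return cls(**d)


@dataclass
class DcmSkeleton:
    """Free-parameter masks for one validated architecture.

    The diagonal self-decay of A is fixed (not a free parameter); the
    masks mark which off-diagonal A, B and C entries are estimated.
    Structurally absent connections are not represented at all and stay
    exactly zero.
    """

    spec: ModelSpec
    region_labels: tuple[str, ...]
    input_labels: tuple[str, ...]
    free_A: np.ndarray  # (n, n) bool, off-diagonal
    free_B: np.ndarray  # (m, n, n) bool
    free_C: np.ndarray  # (n, m) bool

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_free(self) -> int:
        return int(self.free_A.sum() + self.free_B.sum() + self.free_C.sum())

    def parameter_names(self) -> list[str]:
        names = []
        rl = self.region_labels
        for i, j in np.argwhere(self.free_A):
            names.append(f"A[{rl[i]}<-{rl[j]}]")
        for k, i, j in np.argwhere(self.free_B):
            names.append(f"B[{self.input_labels[k]}:{rl[i]}<-{rl[j]}]")
        for i, k in np.argwhere(self.free_C):
            names.append(f"C[{rl[i]}<-{self.input_labels[k]}]")
        return names


def _structural_edges(region_labels: tuple[str, ...]) -> set[tuple[int, int]]:
    """Within-hemisphere reciprocal VC<->SPL edges as (dst, src) index pairs."""
    idx = {r: i for i, r in enumerate(region_labels)}
    edges = set()
    for side in ("L", "R"):
        vc, spl = idx[f"VC_{side}"], idx[f"SPL_{side}"]
        edges.add((vc, spl))
        edges.add((spl, vc))
    return edges


def validate(spec: ModelSpec,
             input_labels: tuple[str, ...] = ("attention",)) -> DcmSkeleton:
    """Check a ModelSpec and emit its free-parameter masks.

    Rejects inputs to unknown regions and modulation of edges absent
    from the intrinsic structure (e.g. interhemispheric links).
    """
    rl = CANONICAL_REGIONS
    idx = {r: i for i, r in enumerate(rl)}
    n, m = len(rl), len(input_labels)
    if spec.input_family not in _INPUT_FAMILIES:
        raise ValueError(
            f"unknown input_family {spec.input_family!r}; "
            f"expected one of {_INPUT_FAMILIES}"
        )
    if spec.modulation not in _MODULATIONS:
        raise ValueError(
            f"unknown modulation {spec.modulation!r}; "
            f"expected one of {_MODULATIONS}"
        )
    if spec.hemisphere not in _HEMI:
        raise ValueError(f"unknown hemisphere {spec.hemisphere!r}")

    edges = _structural_edges(rl)
    free_A = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        free_A[i, j] = True

    free_B = np.zeros((m, n, n), dtype=bool)
    for src, dst in spec.resolved_modulated_edges():
        if src not in idx or dst not in idx:
            raise ValueError(f"modulated edge ({src}, {dst}) names unknown region")
        i, j = idx[dst], idx[src]
        if (i, j) not in edges:
            raise ValueError(
                f"model {spec.name!r} modulates {src}->{dst}, which is not a "
                "structural connection (no interhemispheric links exist)"
            )
        free_B[:, i, j] = True

    free_C = np.zeros((n, m), dtype=bool)
    for tgt in spec.resolved_input_targets():
        if tgt not in idx:
            raise ValueError(f"input target {tgt!r} is not a known region")
        free_C[idx[tgt], :] = True

    return DcmSkeleton(
        spec=spec, region_labels=rl, input_labels=tuple(input_labels),
        free_A=free_A, free_B=free_B, free_C=free_C,
    )


def mirror(spec: ModelSpec, name: str | None = None) -> ModelSpec:
    """Swap hemispheres (an involution mapping M_aL onto M_aR)."""
    def swap(label: str) -> str:
        return label.replace("_L", "_#").replace("_R", "_L").replace("_#", "_R")

    other = {"left": "right", "right": "left"}[spec.hemisphere]
    return replace(
        spec,
        name=name if name is not None else spec.name,
        hemisphere=other,
        input_targets=None if spec.input_targets is None
        else tuple(swap(t) for t in spec.input_targets),
        modulated_edges=None if spec.modulated_edges is None
        else tuple((swap(a), swap(b)) for a, b in spec.modulated_edges),
    )


def attention_pair() -> tuple[ModelSpec, ModelSpec]:
    """The neurofeedback pair (M_aL, M_aR).

    Attending the *left* visual field engages the right hemisphere, so
    M_aL puts the attention input on the right SPL and modulates the
    right VC<->SPL coupling in both directions; M_aR mirrors this onto
    the left hemisphere.
    """
    m_al = ModelSpec(name="M_aL", input_family="SPL", modulation="both",
                     hemisphere="right")
    return m_al, mirror(m_al, name="M_aR")


def model_family(hemisphere: str = "right") -> list[ModelSpec]:
    """The 12-model comparison grid, row-major over the 3 x 4 grid.

    Rows: attention input to SPL (models 1-4), VC (5-8), both (9-12).
    Columns: modulation of both directions, top-down only, bottom-up
    only, none.  Model 1 equals the neurofeedback architecture.
    """
    specs = []
    k = 0
    for fam in _INPUT_FAMILIES:
        for mod in _MODULATIONS:
            k += 1
            specs.append(ModelSpec(
                name=f"model_{k:02d}", input_family=fam, modulation=mod,
                hemisphere=hemisphere,
            ))
    return specs


def build_params(
    skeleton: DcmSkeleton,
    a: float = 0.3,
    b: float = 0.4,
    c: float = 0.3,
    self_decay: float = -0.5,
) -> ConnectivityParams:
    """Fill a skeleton's free entries with scalar ground-truth values.

    ``a``: intrinsic VC<->SPL coupling (Hz), ``b``: modulatory increase
    (Hz), ``c``: direct input weight (Hz per unit input).
    """
    n, m = skeleton.n_regions, len(skeleton.input_labels)
    A = np.eye(n) * self_decay
    A[skeleton.free_A] = a
    B = np.zeros((m, n, n))
    B[skeleton.free_B] = b
    C = np.zeros((n, m))
    C[skeleton.free_C] = c
    return ConnectivityParams(
        A=A, B=B, C=C,
        region_labels=skeleton.region_labels,
        input_labels=skeleton.input_labels,
    )
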