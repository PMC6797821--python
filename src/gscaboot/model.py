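"""Model specification for generalized structured component analysis (GSCA).

A GSCA model is a component-based structural equation model: each latent
construct is an exact weighted composite (component) of its block of
indicators, and directed paths connect components.  The specification is
purely structural — it records which weights, loadings and path coefficients
are free — and is shared by the estimator, the bootstrap machinery and the
population model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["ModelSpec", "parse_model_config"]


@dataclass(frozen=True)
class ModelSpec:
    """Measurement and structural pattern of a GSCA model.

    Parameters
    ----------
    blocks : dict[str, list[str]]
        Mapping component label -> ordered list of indicator labels.  Every
        indicator belongs to exactly one block.
    paths : list[tuple[str, str]]
        Directed structural paths ``(source, target)`` between components.
        Self-paths are not allowed.
    """

    blocks: dict[str, list[str]]
    paths: list[tuple[str, str]]
    indicators: tuple[str, ...] = field(init=False)
    components: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        comps = tuple(self.blocks)
        inds: list[str] = []
        for comp, members in self.blocks.items():
            if len(members) == 0:
                raise ValueError(f"block {comp!r} has no indicators")
            inds.extend(members)
        if len(set(inds)) != len(inds):
            raise ValueError("an indicator may belong to exactly one block")
        for src, dst in self.paths:
            if src == dst:
                raise ValueError(f"self-path {src!r} -> {dst!r} is not allowed")
            if src not in comps or dst not in comps:
                raise ValueError(f"path {src!r} -> {dst!r} references unknown component")
        if len(set(self.paths)) != len(self.paths):
            raise ValueError("duplicate path")
        object.__setattr__(self, "indicators", tuple(inds))
        object.__setattr__(self, "components", comps)

    # ---- sizes -------------------------------------------------------------
    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def n_components(self) -> int:
        return len(self.components)

    # ---- index helpers -----------------------------------------------------
    def indicator_index(self, label: str) -> int:
        return self.indicators.index(label)

    def component_index(self, label: str) -> int:
        return self.components.index(label)

    @property
    def block_of(self) -> dict[str, str]:
        """Map indicator label -> component label."""
        return {ind: comp for comp, members in self.blocks.items() for ind in members}

    def block_indices(self, comp: str) -> np.ndarray:
        """Column indices (into the indicator ordering) of a component's block."""
        return np.array([self.indicator_index(i) for i in self.blocks[comp]], dtype=int)

    # ---- binary patterns ---------------------------------------------------
    @property
    def weight_pattern(self) -> np.ndarray:
        """J x P boolean mask of free weights (block diagonal)."""
        W = np.zeros((self.n_indicators, self.n_components), dtype=bool)
        for p, comp in enumerate(self.components):
            W[self.block_indices(comp), p] = True
        return W

    @property
    def loading_pattern(self) -> np.ndarray:
        """P x J boolean mask of free loadings (transpose of the weight mask)."""
        return self.weight_pattern.T

    @property
    def path_pattern(self) -> np.ndarray:
        """P x P boolean mask; entry (i, j) is the free path component_i -> component_j."""
        B = np.zeros((self.n_components, self.n_components), dtype=bool)
        for src, dst in self.paths:
            B[self.component_index(src), self.component_index(dst)] = True
        return B

    def predecessors(self, comp: str) -> list[str]:
        return [src for src, dst in self.paths if dst == comp]

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(c for c in self.components if self.predecessors(c))

    # ---- labelled free parameters -------------------------------------------
    @property
    def parameter_labels(self) -> tuple[str, ...]:
        """Labels of all free loadings then all free paths (the theta ordering)."""
        labels = [f"loading:{ind}" for ind in self.indicators]
        labels += [f"path:{src}->{dst}" for src, dst in self.paths]
        return tuple(labels)


def parse_model_config(text: str) -> ModelSpec:
    """Parse a YAML model configuration into a :class:`ModelSpec`.

    Expected layout::

        blocks:
          gamma1: [x1, x2, x3]
          gamma2: [x4, x5, x6]
        paths:
          - gamma1 -> gamma2
    """
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "blocks" not in cfg:
        raise ValueError("model config must contain a 'blocks' mapping")
    blocks = {str(k): [str(v) for v in vs] for k, vs in cfg["blocks"].items()}
    paths: list[tuple[str, str]] = []
    for entry in cfg.get("paths") or []:
        parts = [p.strip() for p in str(entry).split("->")]
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"cannot parse path entry {entry!r}; expected 'from -> to'")
        paths.append((parts[0], parts[1]))
    return ModelSpec(blocks=blocks, paths=paths)
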