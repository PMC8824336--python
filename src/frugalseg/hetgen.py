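"""Online heterogenisation of a homogeneously labeled dataset.

Structured label-ablation experiments need many distinct partially labeled
datasets derived from one fully labeled source.  For each class in a chosen
subset ``d`` of the foreground classes, a share ``rho = P / S`` of the ``S``
samples has that class's mask dropped; draws are independent across classes,
so a sample can lose one, several or all of its eligible masks.  Labels are
dropped *online*: the source dataset on disk is never modified, a
:class:`HeterogeneousView` recomputes the dropped version of each sample on
access, and a per-iteration :class:`SampleMemory` guarantees that repeated
queries of the same sample within one iteration (e.g. under oversampling)
see bit-identical labels.

Two persistence modes exist for the memory reset at iteration boundaries:

* ``per_epoch`` — the drop plan is redrawn each epoch (same ``rho``, fresh
  randomness), matching an online generator emptied after every training
  iteration;
* ``whole_training`` — the plan is a pure function of the seed and never
  changes, giving a fixed partially labeled dataset.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DropSpec",
    "SampleMemory",
    "HeterogeneousView",
    "round_half_away",
    "plan_drops",
    "apply_drops",
    "reset_memory",
    "recompute_background",
    "heterogenize_manifest",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (so 2.5 -> 3)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -round_half_away(-x)


@dataclass(frozen=True)
class DropSpec:
    """Which classes may lose labels, how many, and how reproducibly.

    ``drop_classes`` are channel indices eligible for dropping (foreground
    only — never the background channel); ``rho`` is the relative share of
    samples that lose each eligible class, so the absolute count is
    ``P = round(rho * S)`` per class.
    """

    drop_classes: tuple[int, ...]
    rho: float
    seed: int = 0
    persistence: str = "per_epoch"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.persistence not in ("per_epoch", "whole_training"):
            raise ValueError(f"unknown persistence {self.persistence!r}")
        object.__setattr__(self, "drop_classes",
                           tuple(sorted(set(self.drop_classes))))


class SampleMemory:
    """Per-iteration store of realised per-sample keep/drop flags.

    An entry is written the first time a sample is queried within an
    iteration and is immutable until :meth:`reset`, so oversampled queries
    always return identical flags.
    """

    def __init__(self) -> None:
        self._entries: dict = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, sample_id) -> bool:
        return sample_id in self._entries

    def get(self, sample_id):
        flags = self._entries.get(sample_id)
        return None if flags is None else flags.copy()

    def put(self, sample_id, flags: np.ndarray) -> None:
        if sample_id in self._entries:
            raise KeyError(f"memory entry for {sample_id!r} already written "
                           "this iteration (entries are immutable)")
        self._entries[sample_id] = np.asarray(flags, dtype=np.uint8).copy()

    def reset(self) -> None:
        self._entries.clear()


def plan_drops(sample_ids: Sequence, spec: DropSpec, num_classes: int,
               *, epoch: int = 0) -> dict:
    """Draw the drop plan: ``sample_id -> mask vector`` of length C.

    For every class in ``spec.drop_classes`` exactly ``P = round(rho * S)``
    distinct samples get that class's flag cleared; draws are independent
    across classes and fully determined by ``(seed, epoch, class)``, so the
    same seed reproduces the same plan in any process.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("sample_ids must be nonempty")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample_ids contain duplicates")
    for c in spec.drop_classes:
        if not 0 <= c < num_classes:
            raise ValueError(f"drop class {c} out of range for C={num_classes}")
    S = len(sample_ids)
    P = round_half_away(spec.rho * S)
    eff_epoch = 0 if spec.persistence == "whole_training" else epoch
    flags = {sid: np.ones(num_classes, dtype=np.uint8) for sid in sample_ids}
    for c in spec.drop_classes:
        rng = np.random.default_rng([spec.seed, eff_epoch, c])
        for i in rng.choice(S, size=P, replace=False):
            flags[sample_ids[i]][c] = 0
    return flags


def recompute_background(gt: np.ndarray, flags: np.ndarray,
                         background_index: int) -> np.ndarray:
    """Set the background channel to the complement of the union of the
    *present* foreground masks (in place on a copy passed in).

    This reproduces the naive background definition under which a dropped
    foreground region silently becomes background — the very pathology the
    asymmetric loss exists to counter.
    """
    fg = [c for c in range(gt.shape[2]) if c != background_index]
    present = [c for c in fg if flags[c]]
    if present:
        union = gt[..., present].max(axis=-1)
    else:
        union = np.zeros(gt.shape[:2], dtype=gt.dtype)
    gt[..., background_index] = 1 - union
    return gt


class HeterogeneousView:
    """Lazy heterogeneous view over a homogeneously labeled dataset.

    The view never mutates the source; :meth:`apply` returns a modified
    copy of the ground truth with dropped channels zeroed, the background
    channel recomputed, and the mask vector reflecting availability.

    Parameters
    ----------
    sample_ids
        Identifiers of all samples governed by the view (defines ``S``).
    num_classes
        Total channel count C, including the background channel.
    spec
        The drop specification.
    background_index
        Background channel to recompute after dropping, or None to leave
        channels untouched apart from zeroing.
    strict_background
        If True, a sample missing any foreground mask gets
        ``m_background = 0`` and a zeroed background channel instead of the
        recomputed complement.
    """

    def __init__(self, sample_ids: Sequence, num_classes: int, spec: DropSpec,
                 *, background_index: int | None = None,
                 strict_background: bool = False) -> None:
        self.sample_ids = list(sample_ids)
        self.num_classes = num_classes
        self.spec = spec
        self.background_index = background_index
        self.strict_background = strict_background
        self.memory = SampleMemory()
        self._epoch = 0
        self._plan = plan_drops(self.sample_ids, spec, num_classes, epoch=0)

    @property
    def epoch(self) -> int:
        return self._epoch

    def flags_for(self, sample_id) -> np.ndarray:
        """Keep/drop flags for a sample this iteration (consults memory)."""
        flags = self.memory.get(sample_id)
        if flags is None:
            if sample_id not in self._plan:
                raise KeyError(f"unknown sample id {sample_id!r}")
            flags = self._plan[sample_id].copy()
            self.memory.put(sample_id, flags)
        return flags

    def apply(self, sample_id, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(modified ground truth, mask vector)`` for one sample."""
        gt = np.asarray(gt)
        if gt.ndim != 3 or gt.shape[2] != self.num_classes:
            raise ValueError(
                f"ground truth must be (h, w, {self.num_classes})")
        flags = self.flags_for(sample_id)
        out = gt.copy()
        m = flags.copy()
        for c in range(self.num_classes):
            if not flags[c]:
                out[..., c] = 0
        if self.background_index is not None:
            bg = self.background_index
            if self.strict_background and not flags.all():
                out[..., bg] = 0
                m[bg] = 0
            else:
                recompute_background(out, flags, bg)
                m[bg] = 1
        return out, m

    def reset_memory(self) -> None:
        """End an iteration: clear the memory; under ``per_epoch`` redraw
        the plan for the next epoch, under ``whole_training`` a no-op."""
        self.memory.reset()
        if self.spec.persistence == "per_epoch":
            self._epoch += 1
            self._plan = plan_drops(self.sample_ids, self.spec,
                                    self.num_classes, epoch=self._epoch)


def apply_drops(sample_id, gt: np.ndarray, view: HeterogeneousView):
    """Functional alias for :meth:`HeterogeneousView.apply`."""
    return view.apply(sample_id, gt)


def reset_memory(view: HeterogeneousView) -> None:
    """Functional alias for :meth:`HeterogeneousView.reset_memory`."""
    view.reset_memory()


def heterogenize_manifest(manifest, spec: DropSpec):
    """Blank the dropped mask cells of a manifest's *training* rows.

    Returns a new :class:`~frugalseg.data_io.Manifest` whose mask-path
    cells for dropped (sample, class) pairs are empty strings; test rows
    are never touched.  This is the offline counterpart of the online view.
    """
    from .data_io import Manifest

    df = manifest.df.copy()
    train_ids = df.loc[df["split"] == "train", "sample_id"].tolist()
    C = len(manifest.class_names)
    plan = plan_drops(train_ids, spec, C)
    for sid, flags in plan.items():
        row = df.index[df["sample_id"] == sid][0]
        for c, name in enumerate(manifest.class_names):
            if not flags[c]:
                df.loc[row, f"mask_{name}"] = ""
    return Manifest(df, class_names=manifest.class_names, root=manifest.root)
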