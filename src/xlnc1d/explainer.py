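"""Additive attributions for the lncRNA output, and their aggregation.

SHAP values are estimated with the expected-gradients estimator: for each
explained sequence x and background reference b, the input gradient of the
lncRNA probability is integrated along the straight path from b to x
(midpoint quadrature), multiplied by (x - b), and averaged over the
background set. The estimate satisfies the additivity (local accuracy)
contract sum(attributions) + base_value ~= p_lncRNA(x), where base_value is
the mean lncRNA probability over the backgrounds; the quadrature error is
well below the 0.05 default tolerance.

Sign convention: positive = pushes the call toward lncRNA (drawn blue),
negative = toward mRNA (red).

Downstream aggregation: per-nucleotide values are the channel sums of the
L x 4 matrix; codon tracks sum three consecutive nucleotide values in each
of the three reading frames; k-mer impact tables average |window sum| over
every sliding window of width k, grouped by k-mer identity and class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from matplotlib.collections import LineCollection
from matplotlib.figure import Figure

from .cnn_model import XlncModel, predict_proba
from .sequence_io import LNCRNA, MRNA, CHANNELS, EncodedDataset, SequenceRecord

DEFAULT_ADDITIVITY_TOL = 0.05


@dataclass
class BackgroundSet:
    """Reference sequences anchoring the attribution expectation."""

    tensor: np.ndarray
    ids: list[str]
    labels: np.ndarray
    seed: int

    def __len__(self) -> int:
        return self.tensor.shape[0]


@dataclass
class AttributionMatrix:
    """SHAP values per position and channel for one sequence (lncRNA output)."""

    values: np.ndarray  # (L, 4) float64
    base_value: float
    seq_id: str
    seq_length: int

    def __post_init__(self):
        if not np.isfinite(self.values).all():
            raise ValueError("attribution values must be finite")


@dataclass
class NucleotideTrack:
    """One attribution value per position (channel-collapsed)."""

    values: np.ndarray
    seq_id: str = ""


@dataclass
class CodonTracks:
    """Codon-level attributions in the three reading frames.

    Frame f holds floor((L - f) / 3) values; the j-th is the sum of
    nucleotide values at positions f+3j .. f+3j+2. Incomplete trailing
    codons are dropped.
    """

    frames: tuple[np.ndarray, np.ndarray, np.ndarray]
    seq_id: str = ""


def select_background(
    dataset: EncodedDataset, n_per_class: int = 175, seed: int = 0
) -> BackgroundSet:
    """Sample n_per_class sequences per class without replacement."""
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for cls, name in ((1, LNCRNA), (0, MRNA)):
        pool = np.flatnonzero(dataset.labels == cls)
        if len(pool) < n_per_class:
            raise ValueError(
                f"class {name} has {len(pool)} sequences, "
                f"need {n_per_class} for the background"
            )
        chosen.extend(rng.choice(pool, size=n_per_class, replace=False).tolist())
    chosen = sorted(chosen)
    ids = [dataset.ids[i] for i in chosen] if dataset.ids else [str(i) for i in chosen]
    return BackgroundSet(
        tensor=dataset.tensor[chosen].copy(),
        ids=ids,
        labels=dataset.labels[chosen].copy(),
        seed=seed,
    )


def _warped_nodes(
    model: XlncModel,
    x: np.ndarray,
    bg: np.ndarray,
    n_steps: int,
    chunk: int,
    n_probe: int = 33,
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights per background, concentrated where the model
    output actually changes along the path.

    The lncRNA probability is probed at ``n_probe`` evenly spaced points
    (forward passes only); nodes are then allocated to the probe segments
    proportionally to |Δp| plus a uniform floor, midpoint rule within each
    segment. Returns (nodes, weights), each (B, n_steps); weights sum to 1
    per background.
    """
    B, L, C = bg.shape
    probe = np.linspace(0.0, 1.0, n_probe, dtype=np.float32)
    diff = x[None] - bg
    pts = (bg[:, None] + probe[None, :, None, None] * diff[:, None]).reshape(
        B * n_probe, L, C
    )
    f = np.empty(B * n_probe)
    for lo in range(0, len(pts), chunk):
        f[lo : lo + chunk] = model.network.predict_proba(pts[lo : lo + chunk])[:, 1]
    f = f.reshape(B, n_probe)
    mass = np.abs(np.diff(f, axis=1)) + 1.0 / (n_probe - 1) * 0.25
    mass /= mass.sum(axis=1, keepdims=True)

    edges = probe.astype(np.float64)
    nodes = np.empty((B, n_steps))
    weights = np.empty((B, n_steps))
    for b in range(B):
        # largest-remainder allocation of n_steps nodes over the segments
        ideal = mass[b] * n_steps
        counts = np.floor(ideal).astype(int)
        short = n_steps - counts.sum()
        if short > 0:
            counts[np.argsort(ideal - counts)[::-1][:short]] += 1
        pos = 0
        for i, n_i in enumerate(counts):
            if n_i == 0:
                continue
            lo, hi = edges[i], edges[i + 1]
            width = (hi - lo) / n_i
            nodes[b, pos : pos + n_i] = lo + (np.arange(n_i) + 0.5) * width
            weights[b, pos : pos + n_i] = width
            pos += n_i
    return nodes, weights


def _path_attributions(
    model: XlncModel, x: np.ndarray, bg: np.ndarray, n_steps: int, chunk: int
) -> np.ndarray:
    """Per-background path-integral attributions (B, L, C), warped midpoints."""
    B, L, C = bg.shape
    nodes, weights = _warped_nodes(model, x, bg, n_steps, chunk)
    diff = x[None] - bg
    points = (
        bg[:, None] + nodes.astype(np.float32)[:, :, None, None] * diff[:, None]
    ).reshape(B * n_steps, L, C)
    grads = np.empty_like(points)
    for lo in range(0, len(points), chunk):
        grads[lo : lo + chunk] = model.network.input_gradient(
            points[lo : lo + chunk], output_index=1
        )
    avg_grad = (
        grads.reshape(B, n_steps, L, C).astype(np.float64)
        * weights[:, :, None, None]
    ).sum(axis=1)
    return diff.astype(np.float64) * avg_grad


def compute_shap(
    model: XlncModel,
    background: BackgroundSet,
    sequences: EncodedDataset,
    n_steps: int = 25,
    chunk: int = 64,
    refine_tol: float = 0.03,
    max_refinements: int = 2,
) -> list[AttributionMatrix]:
    """Expected-gradients SHAP estimates for every sequence in ``sequences``.

    ``n_steps`` is the number of midpoint quadrature nodes per background.
    Each background's path integral has an exactly checkable completeness
    residual |Σ attribution + f(b) − f(x)|; backgrounds whose residual
    exceeds ``refine_tol`` are re-integrated with 4x the nodes, up to
    ``max_refinements`` rounds, so quadrature error stays well below the
    additivity tolerance at near-baseline cost. Cost scales as
    len(background) * n_steps forward+backward passes per sequence,
    evaluated in chunks of ``chunk`` rows.
    """
    if len(background) == 0:
        raise ValueError("background set is empty")
    if background.tensor.shape[1] != sequences.input_length:
        raise ValueError("background and sequences must share the input length")
    bg = background.tensor.astype(np.float32)
    f_bg = predict_proba(model, bg)[:, 1].astype(np.float64)
    base_value = float(f_bg.mean())
    f_x = predict_proba(model, sequences.tensor)[:, 1].astype(np.float64)

    out: list[AttributionMatrix] = []
    ids = sequences.ids or [str(i) for i in range(len(sequences))]
    for s in range(len(sequences)):
        x = sequences.tensor[s].astype(np.float32)
        attr_b = _path_attributions(model, x, bg, n_steps, chunk)
        steps = n_steps
        for _ in range(max_refinements):
            resid = np.abs(attr_b.sum(axis=(1, 2)) + f_bg - f_x[s])
            bad = np.flatnonzero(resid > refine_tol)
            if not len(bad):
                break
            steps *= 4
            attr_b[bad] = _path_attributions(model, x, bg[bad], steps, chunk)
        values = attr_b.mean(axis=0)
        out.append(
            AttributionMatrix(
                values=values,
                base_value=base_value,
                seq_id=ids[s],
                seq_length=int(sequences.lengths[s]),
            )
        )
    return out


def check_additivity(
    model: XlncModel,
    attrs: Sequence[AttributionMatrix],
    sequences: EncodedDataset,
    tol: float = DEFAULT_ADDITIVITY_TOL,
) -> np.ndarray:
    """|sum(attr) + base - p_lncRNA(x)| per sequence; raises if any exceeds tol."""
    probs = predict_proba(model, sequences.tensor)[:, 1]
    errs = np.array(
        [abs(a.values.sum() + a.base_value - p) for a, p in zip(attrs, probs)]
    )
    if (errs > tol).any():
        raise ValueError(
            f"additivity violated: max |error| = {errs.max():.4f} > tol {tol}"
        )
    return errs


def collapse_to_nucleotide(attr: AttributionMatrix) -> NucleotideTrack:
    """Sum the four channels per position; the total is conserved exactly."""
    return NucleotideTrack(values=attr.values.sum(axis=1), seq_id=attr.seq_id)


def codon_aggregate(track: NucleotideTrack) -> CodonTracks:
    """Sum consecutive nucleotide triples in each of the three reading frames."""
    v = np.asarray(track.values, dtype=np.float64)
    L = len(v)
    if L < 3:
        raise ValueError(f"need at least 3 nucleotide values, got {L}")
    frames = []
    for f in range(3):
        n = (L - f) // 3
        frames.append(v[f : f + 3 * n].reshape(n, 3).sum(axis=1))
    return CodonTracks(frames=tuple(frames), seq_id=track.seq_id)


def kmer_impact(
    tracks: Sequence[NucleotideTrack],
    sequences: Sequence[SequenceRecord],
    labels: Sequence[str] | None = None,
    k: int = 3,
    window_agg: Literal["abs-sum", "sum"] = "abs-sum",
) -> pd.DataFrame:
    """Mean |window attribution| per k-mer and class panel.

    Every sliding window of width k (step 1) over the true sequence extent
    contributes |sum of its nucleotide values| (or the raw sum with
    ``window_agg='sum'``); means are grouped by k-mer identity and by class
    (true labels by default). All 4^k k-mers are reported; absent ones get
    count 0 and impact 0. Windows containing ambiguity codes are skipped.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if labels is None:
        labels = [rec.label for rec in sequences]
    if len(tracks) != len(sequences) or len(labels) != len(sequences):
        raise ValueError("tracks, sequences and labels must be aligned")
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for track, rec, label in zip(tracks, sequences, labels):
        if track.seq_id and track.seq_id != rec.id:
            raise ValueError(f"track/sequence id mismatch: {track.seq_id} vs {rec.id}")
        if label not in (LNCRNA, MRNA):
            raise ValueError(f"unknown class label {label!r}")
        L = len(rec.residues)
        v = np.asarray(track.values, dtype=np.float64)[:L]
        if L < k:
            continue
        win = np.lib.stride_tricks.sliding_window_view(v, k).sum(axis=1)
        if window_agg == "abs-sum":
            win = np.abs(win)
        seq = rec.residues
        for p in range(L - k + 1):
            kmer = seq[p : p + k]
            if any(b not in "ACGT" for b in kmer):
                continue
            key = (label, kmer)
            sums[key] = sums.get(key, 0.0) + float(win[p])
            counts[key] = counts.get(key, 0) + 1
    all_kmers = [""]
    for _ in range(k):
        all_kmers = [s + b for s in all_kmers for b in "ACGT"]
    rows = []
    for kmer in all_kmers:
        row = {"kmer": kmer}
        for label in (LNCRNA, MRNA):
            c = counts.get((label, kmer), 0)
            row[f"mean_abs_shap_{label}"] = sums.get((label, kmer), 0.0) / c if c else 0.0
            row[f"count_{label}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PlotSegment:
    start: int
    end: int
    value: float
    color: str  # "blue" (toward lncRNA) or "red" (toward mRNA)


@dataclass
class PlotMetadata:
    """What was drawn: per-frame segment lists (frame -1 = nucleotide track)."""

    segments: dict[int, list[PlotSegment]] = field(default_factory=dict)

    def colors(self) -> set[str]:
        return {s.color for frame in self.segments.values() for s in frame}


def plot_attribution(
    tracks: CodonTracks | NucleotideTrack,
    sequence: SequenceRecord,
    out: str | Path,
) -> PlotMetadata:
    """Render the color-track attribution figure and return segment metadata.

    Positive values are drawn blue (contribution toward lncRNA), negative
    red (toward mRNA); opacity scales with |value|. Codon tracks produce
    three stacked panels, one per reading frame.
    """
    if isinstance(tracks, NucleotideTrack):
        panels = {-1: (np.asarray(tracks.values), 1)}
    else:
        panels = {f: (np.asarray(tracks.frames[f]), 3) for f in range(3)}
    vmax = max((np.abs(v).max() for v, _ in panels.values() if len(v)), default=0.0)
    meta = PlotMetadata()
    fig = Figure(figsize=(10, 1.6 * len(panels)))
    axes = fig.subplots(len(panels), 1, squeeze=False)[:, 0]
    for ax, (frame, (values, width)) in zip(axes, sorted(panels.items())):
        segs, colors = [], []
        meta.segments[frame] = []
        offset = frame if frame >= 0 else 0
        for j, val in enumerate(values):
            start = offset + j * width
            end = start + width
            color = "blue" if val >= 0 else "red"
            alpha = float(abs(val) / vmax) if vmax > 0 else 0.0
            segs.append([(start, 0.5), (end, 0.5)])
            colors.append((*{"blue": (0.0, 0.0, 1.0), "red": (1.0, 0.0, 0.0)}[color], alpha))
            meta.segments[frame].append(PlotSegment(start, end, float(val), color))
        if segs:
            ax.add_collection(LineCollection(segs, colors=colors, linewidths=8))
        ax.set_xlim(0, len(sequence.residues))
        ax.set_ylim(0, 1)
        ax.set_yticks([])
        ax.set_ylabel("nt track" if frame < 0 else f"frame {frame}")
    axes[-1].set_xlabel(f"position in {sequence.id} (nt)")
    fig.suptitle(f"attribution toward lncRNA (blue) vs mRNA (red): {sequence.id}")
    fig.savefig(out)
    return meta


def attributions_to_tsv(
    attrs: Sequence[AttributionMatrix],
    sequences: Sequence[SequenceRecord],
    path: str | Path,
) -> None:
    """Long-format TSV: seq_id, position, nucleotide, shap_value."""
    by_id = {rec.id: rec for rec in sequences}
    rows = []
    for attr in attrs:
        rec = by_id.get(attr.seq_id)
        if rec is None:
            raise ValueError(f"no sequence record for attribution {attr.seq_id!r}")
        nt = collapse_to_nucleotide(attr).values
        for p in range(attr.seq_length):
            rows.append((attr.seq_id, p, rec.residues[p], nt[p]))
    pd.DataFrame(rows, columns=["seq_id", "position", "nucleotide", "shap_value"]).to_csv(
        path, sep="\t", index=False
    )
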