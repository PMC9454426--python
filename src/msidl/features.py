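"""Pooled discriminative-mass bookkeeping and density-preserving embedding.

``dedup_filter`` pools the per-class top masses and separates class-unique
masses from masses shared by several classes; shared masses behave like
measurement artifacts (e.g. residual matrix signal) and are excluded from
downstream feature use. ``embed_densmap`` projects every pixel, restricted
to the unique masses, into 2-D with a supervised density-preserving UMAP
(densMAP) embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .attribute import TopKMasses
from .io import MSIDataset


@dataclass
class MassList:
    """Pooled (class, m/z, score) entries split into class-unique and
    artifact (multi-class) masses. Two masses count as the same when they
    differ by at most one bin width."""

    entries: list[tuple[str, float, float]]
    unique_masses: list[float]
    artifact_masses: list[float]

    def to_dict(self) -> dict:
        return {"entries": [[c, mz, sc] for c, mz, sc in self.entries],
                "unique_masses": self.unique_masses,
                "artifact_masses": self.artifact_masses}


def dedup_filter(topk: TopKMasses, bin_width: float) -> MassList:
    """Split the pooled top-k masses into class-unique and artifact masses.

    Masses from different classes equal within one bin width are chained into
    one group; any group touched by more than one class is flagged artifact
    and its masses are excluded from downstream features.
    """
    entries = topk.pooled()
    if not entries:
        raise ValueError("empty top-k mass list")
    order = sorted(range(len(entries)), key=lambda i: entries[i][1])
    groups: list[list[int]] = []
    for i in order:
        if groups and entries[i][1] - entries[groups[-1][-1]][1] <= bin_width:
            groups[-1].append(i)
        else:
            groups.append([i])
    unique, artifact = [], []
    for g in groups:
        classes = {entries[i][0] for i in g}
        mzs = sorted({entries[i][1] for i in g})
        (unique if len(classes) == 1 else artifact).extend(mzs)
    return MassList(entries=[entries[i] for i in order],
                    unique_masses=sorted(unique),
                    artifact_masses=sorted(artifact))


@dataclass
class EmbeddingResult:
    """2-D embedding of every pixel with labels and core ids passed through."""

    coords2d: np.ndarray           # (n, 2)
    labels: np.ndarray
    core_ids: np.ndarray


def embed_densmap(dataset: MSIDataset, features: MassList,
                  labels: np.ndarray | None = None, seed: int = 0,
                  supervision: float = 0.5, n_neighbors: int = 15) -> EmbeddingResult:
    """Supervised densMAP embedding of pixels restricted to the unique masses.

    Each pixel is reduced to its intensities at the bins nearest the
    class-unique masses, then embedded into 2-D by UMAP with density
    preservation (densmap) and categorical label supervision of strength
    ``supervision`` (0 = unsupervised, 1 = labels dominate). Seeded and
    reproducible for a fixed seed.
    """
    import umap

    if not features.unique_masses:
        raise ValueError("no unique masses to embed on")
    if dataset.n_pixels < 2:
        raise ValueError("need at least 2 pixels to embed")
    if labels is None:
        labels = dataset.labels
    bins = dataset.scheme.bin_index(np.asarray(features.unique_masses))
    bins = bins[bins >= 0]
    X = dataset.intensities[:, bins].astype(np.float64)
    classes = sorted(set(labels.tolist()))
    y = np.array([classes.index(l) for l in labels])
    n_nb = min(n_neighbors, dataset.n_pixels - 1)
    emb = umap.UMAP(n_components=2, densmap=True, random_state=seed,
                    n_neighbors=n_nb, target_weight=supervision,
                    ).fit_transform(X, y=y)
    return EmbeddingResult(coords2d=np.asarray(emb, dtype=np.float64),
                           labels=np.asarray(labels, dtype=object).copy(),
                           core_ids=np.asarray(dataset.core_ids, dtype=object).copy())


def save_embedding(result: EmbeddingResult, path: str) -> None:
    """TSV export: ``x2d  y2d  class  core_id``."""
    with open(path, "w") as fh:
        fh.write("x2d\ty2d\tclass\tcore_id\n")
        for (x, y), lab, cid in zip(result.coords2d, result.labels, result.core_ids):
            fh.write(f"{x:.6g}\t{y:.6g}\t{lab}\t{cid}\n")


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>densMAP embedding</title></head>
<body><h3>densMAP embedding (hover a point for its core)</h3>
<canvas id="c" width="800" height="800" style="border:1px solid #888"></canvas>
<div id="info">&nbsp;</div>
<script>
const pts = __POINTS__;
const classes = [...new Set(pts.map(p => p.l))].sort();
const palette = ["#1f77b4","#ff7f0e","#2ca02c","#d62728","#9467bd",
                 "#8c564b","#e377c2","#7f7f7f","#bcbd22","#17becf"];
const xs = pts.map(p=>p.x), ys = pts.map(p=>p.y);
const xmin=Math.min(...xs), xmax=Math.max(...xs);
const ymin=Math.min(...ys), ymax=Math.max(...ys);
const sc = p => [20+760*(p.x-xmin)/(xmax-xmin||1), 780-760*(p.y-ymin)/(ymax-ymin||1)];
const ctx = document.getElementById("c").getContext("2d");
for (const p of pts) {
  const [cx, cy] = sc(p);
  ctx.fillStyle = palette[classes.indexOf(p.l) % palette.length];
  ctx.beginPath(); ctx.arc(cx, cy, 3, 0, 6.283); ctx.fill();
}
document.getElementById("c").addEventListener("mousemove", ev => {
  const r = ev.target.getBoundingClientRect();
  const mx = ev.clientX-r.left, my = ev.clientY-r.top;
  let best=null, bd=64;
  for (const p of pts) { const [cx,cy]=sc(p);
    const d=(cx-mx)**2+(cy-my)**2; if (d<bd) {bd=d; best=p;} }
  document.getElementById("info").textContent =
    best ? `core ${best.c} (${best.l})` : "\\u00a0";
});
</script></body></html>
"""


def save_embedding_html(result: EmbeddingResult, path: str) -> None:
    """Self-contained interactive scatter (hover shows the core id)."""
    pts = [{"x": float(x), "y": float(y), "l": str(l), "c": str(c)}
           for (x, y), l, c in zip(result.coords2d, result.labels, result.core_ids)]
    with open(path, "w") as fh:
        fh.write(_HTML_TEMPLATE.replace("__POINTS__", json.dumps(pts)))
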