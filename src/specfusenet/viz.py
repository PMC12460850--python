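"""Figures: confusion-matrix heatmaps and t-SNE latent embeddings.

Figures are artifacts for inspection; every quantitative check in the
package runs on the underlying arrays/CSVs, never on images.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_confusion", "embed_latents", "tsne_coordinates"]


def plot_confusion(report, class_names, path) -> Path:
    """Heatmap of the confusion matrix with overall accuracy in the title."""
    cm = np.asarray(report.confusion_matrix)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    fig, ax = plt.subplots(figsize=(max(4, k * 0.45), max(3.5, k * 0.4)))
    im = ax.imshow(cm, cmap="Blues")
    ax.set_xticks(range(k), class_names, rotation=90, fontsize=7)
    ax.set_yticks(range(k), class_names, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"overall accuracy {report.accuracy:.2f}%")
    if k <= 30:
        for i in range(k):
            for j in range(k):
                if cm[i, j]:
                    ax.text(j, i, str(cm[i, j]), ha="center", va="center",
                            fontsize=6,
                            color="white" if cm[i, j] > cm.max() / 2 else "black")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def tsne_coordinates(latents: np.ndarray, seed: int = 0,
                     perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE of latent vectors (established implementation, fixed seed).

    Perplexity is shrunk automatically (with a warning) when the sample
    count cannot support the requested value.
    """
    from sklearn.manifold import TSNE

    n = latents.shape[0]
    max_perp = max((n - 1) / 3.0, 1.0)
    if perplexity >= max_perp:
        warnings.warn(f"perplexity {perplexity} too large for n={n}; "
                      f"shrinking to {max_perp:.1f}")
        perplexity = max_perp
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(np.asarray(latents, dtype=float))


def embed_latents(named_latents: dict[str, np.ndarray], labels, out_dir,
                  seed: int = 0, perplexity: float = 30.0) -> tuple[Path, Path]:
    """Side-by-side t-SNE panels per model + a coordinates CSV.

    `named_latents` maps model name -> (n, d) latent matrix; all share
    the same label vector.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels)
    frames = []
    fig, axes = plt.subplots(1, len(named_latents),
                             figsize=(5 * len(named_latents), 4.5),
                             squeeze=False)
    for ax, (name, latents) in zip(axes[0], named_latents.items()):
        coords = tsne_coordinates(latents, seed=seed, perplexity=perplexity)
        ax.scatter(coords[:, 0], coords[:, 1], c=labels, cmap="tab20", s=8)
        ax.set_title(name)
        frames.append(pd.DataFrame({"model": name, "tsne_1": coords[:, 0],
                                    "tsne_2": coords[:, 1], "label": labels}))
    fig.tight_layout()
    fig_path = out_dir / "latent_tsne.png"
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    csv_path = out_dir / "latent_tsne.csv"
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    return fig_path, csv_path
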