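"""Reconstruction figures: original, masked and reconstructed traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ecg_io import LEAD_NAMES
from .patching import PATCH_LENGTH, PATCHES_PER_LEAD, patchify, unpatchify


def plot_reconstruction(model, record, mask, leads=("II", "V5"),
                        paste_visible: bool = True):
    """Three-panel figure per selected lead: original / masked / reconstructed.

    The masked panel blanks hidden patches; the reconstruction panel, by
    the usual masked-autoencoder convention, pastes the visible patches
    from the input over the decoder output (``paste_visible=False`` shows
    the raw decoder output everywhere).
    """
    from .ecg_io import normalize

    rec = normalize(record)
    patch_set = patchify(rec)
    pred = model.reconstruct(patch_set, mask)
    recon_patches = np.array(pred)
    if paste_visible:
        recon_patches[mask.visible_indices] = patch_set.patches[
            mask.visible_indices
        ]
    recon = unpatchify(recon_patches)
    maskb = mask.bool_mask().reshape(12, PATCHES_PER_LEAD)
    masked_signal = rec.signal.copy()
    for lead in range(12):
        for t in range(PATCHES_PER_LEAD):
            if maskb[lead, t]:
                masked_signal[lead, t * PATCH_LENGTH:(t + 1) * PATCH_LENGTH] = np.nan

    lead_idx = [LEAD_NAMES.index(name) for name in leads]
    fig, axes = plt.subplots(len(lead_idx), 3, figsize=(12, 2.2 * len(lead_idx)),
                             squeeze=False, sharex=True)
    t = np.arange(rec.signal.shape[1]) / rec.sampling_rate
    for row, li in enumerate(lead_idx):
        panels = [
            (rec.signal[li], "original"),
            (masked_signal[li], "masked"),
            (recon[li], "reconstructed"),
        ]
        for col, (trace, title) in enumerate(panels):
            ax = axes[row, col]
            ax.plot(t, trace, lw=0.6, color="tab:blue")
            if row == 0:
                ax.set_title(title)
            if col == 0:
                ax.set_ylabel(LEAD_NAMES[li])
    axes[-1, 1].set_xlabel("time (s)")
    fig.tight_layout()
    return fig
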