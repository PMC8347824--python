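"""Shared fixtures: phantom banks, a small convnet for Grad-CAM oracles,
and the expensive end-to-end training run (computed once per session)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import otoshuffle as osh
from otoshuffle import nn

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

# problem sizes for the synthetic study: phantoms are standardized to 72 px
# and trained on 64-px patches (the library defaults of 270/256 hold for
# full-resolution clinical-style use; the smaller sizes keep the synthetic
# study tractable on one CPU)
STD_SIZE = 72
PATCH = 64


class TinyConvNet(nn.Module):
    """Three stride-2/2/1 conv-BN-ReLU blocks + GAP head; its last conv map
    is 16x16 on a 64-px patch, fine enough to localize lesions."""

    def __init__(self, num_classes=2, ch=8, seed=0):
        super().__init__()
        r = np.random.default_rng(seed)
        self.c1 = nn.Conv2d(3, ch, 3, 2, 1, rng=r)
        self.b1 = nn.BatchNorm2d(ch)
        self.c2 = nn.Conv2d(ch, ch, 3, 2, 1, rng=r)
        self.b2 = nn.BatchNorm2d(ch)
        self.c3 = nn.Conv2d(ch, ch, 3, 1, 1, rng=r)
        self.b3 = nn.BatchNorm2d(ch)
        self.fc = nn.Linear(ch, num_classes, rng=r)
        self._last_feature_map = None

    def forward(self, x):
        h = nn.relu(self.b1(self.c1(x)))
        h = nn.relu(self.b2(self.c2(h)))
        h = nn.relu(self.b3(self.c3(h)))
        self._last_feature_map = h
        return self.fc(nn.global_avg_pool(h))

    @property
    def last_feature_map(self):
        return self._last_feature_map


def standardize_patches(images, size=STD_SIZE, patch=PATCH):
    """Raw phantoms -> centre-cropped eval patches + boxes."""
    boxes = [osh.find_content_box(im.pixels) for im in images]
    X = np.stack([osh.eval_patch(osh.standardize(im.pixels, b, size=size), patch)
                  for im, b in zip(images, boxes)])
    return X, boxes


def lesion_bbox_in_patch(image, box, size=STD_SIZE, patch=PATCH, pad_frac=0.15):
    """Map a lesion bounding box from frame coordinates into the
    standardized centre-crop patch, padded to include the lesion margin."""
    t, l, h, w = image.meta["lesion_bbox"]
    t -= pad_frac * h
    l -= pad_frac * w
    h *= 1 + 2 * pad_frac
    w *= 1 + 2 * pad_frac
    sy, sx = size / box.height, size / box.width
    off = (size - patch) // 2
    top = (t - box.top) * sy - off
    left = (l - box.left) * sx - off
    return (int(max(top, 0)), int(max(left, 0)), int(min(h * sy, patch)), int(min(w * sx, patch)))


@pytest.fixture(scope="session")
def phantom_bank():
    """40 mixed-label phantoms at the default canvas, reused across tests."""
    images, manifest = osh.generate_dataset(40, osh.PhantomParams(seed=123))
    return images, manifest


@pytest.fixture(scope="session")
def e2e_run():
    """The full synthetic study: 1000 phantoms under the default prevalence
    mix, 800/200 train/test split, resnet18+shuffle trained on 64-px
    patches.  Shared by the acceptance and Grad-CAM suites."""
    images, _ = osh.generate_dataset(1000, osh.PhantomParams(seed=42))
    X = osh.standardize_batch([im.pixels for im in images], size=STD_SIZE)
    y = np.array([im.label for im in images])
    clf = osh.OtoscopyClassifier(
        backbone="resnet18", attention="shuffle", patch_size=PATCH,
        epochs=6, batch_size=32, lr=1e-3, optimizer="adam", seed=0,
    )
    clf.fit(X[:800], y[:800])
    pred = clf.predict(X[800:])
    acc = float(np.mean(pred == y[800:]))
    return {"clf": clf, "X": X, "y": y, "test_pred": pred, "test_acc": acc, "images": images}


@pytest.fixture(scope="session")
def lesion_study():
    """Paired normal/COM phantoms (same sub-seed, so the frames differ only
    in the perforation) with a trained TinyConvNet at >=95% accuracy."""
    params = osh.PhantomParams(seed=11)
    seeds = np.random.default_rng(5).integers(0, 2**31, 120)
    images = []
    for s in seeds:
        images.append(osh.render_phantom("normal", params, rng=int(s)))
        images.append(osh.render_phantom("COM", params, rng=int(s)))
    X, boxes = standardize_patches(images)
    y = np.array([0 if im.label == "normal" else 1 for im in images])
    Xtr, ytr = X[:200], y[:200]
    net = TinyConvNet(num_classes=2, ch=8, seed=0)
    opt = nn.Adam(net.parameters(), lr=3e-3, weight_decay=1e-4)
    for epoch in range(30):
        if epoch == 20:
            opt.lr = 1e-3
        order = np.random.default_rng(epoch).permutation(len(Xtr))
        for start in range(0, len(Xtr), 32):
            idx = order[start : start + 32]
            loss = nn.softmax_cross_entropy(net(nn.Tensor(Xtr[idx].transpose(0, 3, 1, 2))), ytr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
    net.eval()
    acc = float((net(nn.Tensor(X[200:].transpose(0, 3, 1, 2))).data.argmax(1) == y[200:]).mean())
    return {"net": net, "images": images, "boxes": boxes, "X": X, "y": y, "test_acc": acc}
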