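# otoshuffle

Middle-ear disease classification from endoscopic tympanic-membrane images,
built around residual networks augmented with a **shuffle attention module**
— a 3-D multiplicative gate assembled from a space-to-depth rearrangement, a
1×1 channel-compression convolution, a sigmoid, and nearest-neighbour
upsampling. The package covers the full workflow: black-margin removal and
augmentation, the model zoo (ResNet18/50, optionally gated per residual
block by CBAM or the shuffle module), Grad-CAM saliency for visual
verification, stratified k-fold evaluation with a fixed test set, and
statistics for two-pass assistive reader studies. Because clinical otoscopy
archives are rarely shareable, a synthetic phantom generator renders
labeled stand-in endoscope frames for the four diagnoses (normal, otitis
media with effusion, chronic otitis media, cholesteatoma), so the entire
pipeline runs and is tested without patient data.

The intended users are researchers prototyping otologic image classifiers
and anyone who needs a dependency-light, fully reproducible reference
implementation of shuffle attention: the tensor engine is a small NumPy
reverse-mode autodiff written for this package, so everything runs on one
CPU with no deep-learning framework installed.

## The model

For a feature map `x ∈ R^{C×H×W}` produced by a residual block, the shuffle
attention gate is

```
s = space_to_depth(x)            # 4C × H/2 × W/2, lossless 2×2 re-packing
a = sigmoid(conv1x1(s))          # 4C → C channels, bias-free
m = upsample_nearest2x(a)        # C × H × W, every value in (0,1)
y = x ⊙ m
```

The space-to-depth step folds each 2×2 spatial block into four channels, so
one cheap channel-wise 1×1 convolution mixes local spatial context *and*
channel context into a full 3-D attention map — unlike CBAM, whose spatial
map is shared across channels. A gate is appended after every residual
block (8 for ResNet18, 16 for ResNet50). The extra parameters are exactly
`Σ 4C²` over the gated widths (64,64,128,128,256,256,512,512 for ResNet18),
i.e. 2,785,280.

## Worked example

```python
import numpy as np
import otoshuffle as osh

# 1000 phantom endoscope frames under the clinical prevalence mix
images, manifest = osh.generate_dataset(1000, osh.PhantomParams(seed=42))

# margin-crop and resize; small working resolution keeps this CPU-friendly
X = osh.standardize_batch([im.pixels for im in images], size=72)
y = np.array([im.label for im in images])

clf = osh.OtoscopyClassifier(backbone="resnet18", attention="shuffle",
                             patch_size=64, epochs=6, seed=0)
clf.fit(X[:800], y[:800])
acc = clf.score(X[800:], y[800:])
print(f"held-out accuracy: {acc:.3f}")
cm = osh.confusion(y[800:], clf.predict(X[800:]), labels=osh.LABELS)
print(cm.to_dataframe())
```

This prints `held-out accuracy: 0.950` and a 4×4 confusion matrix whose
rows are the true diagnoses and columns the predictions; the trace divided
by 200 reproduces the accuracy. Phantom classes are rendered with the
diagnostic cue of each disease (amber effusion tint, perforation hole,
attic erosion debris), so a correctly wired network separates them well
above the 53% majority-class rate.

Parameter accounting for the five published variants:

```
$ otoshuffle params --backbone resnet18 --attention shuffle
resnet18+shuffle: 13963844 parameters (13 M)
```

Grad-CAM verification from the command line:

```
$ otoshuffle generate --n 400 --out phantoms --seed 0
$ otoshuffle train --data phantoms --attention shuffle --seed 0 --out run
$ otoshuffle explain --checkpoint run/models/model.npz --image phantoms/phantom_00003.png --class 2 --out heat.png
```

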