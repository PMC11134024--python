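"""Render synthetic eye images and extract convolutional features.

The tiny backbone is used here; swapping BackboneConfig(variant="vgg19")
gives the full 4,096-feature VGG-19 contract (slower, forward-only).
"""

from gazetune import BackboneConfig, build_backbone, extract_features
from gazetune import generate_eye_images
from gazetune.fda import ImageAugmentConfig, augment_image

images = generate_eye_images(n=8, size=32, seed=0)
print(f"rendered {len(images)} grayscale eye images "
      f"({images[0].pixels.shape[0]}x{images[0].pixels.shape[1]}, "
      f"head pose e.g. {images[0].head_pose.round(1)})")

aug = augment_image(images[0], ImageAugmentConfig(), seed=1)
print("augmented copy: rotation + noise, intensities stay in "
      f"[{aug.pixels.min():.2f}, {aug.pixels.max():.2f}]")

extractor = build_backbone(BackboneConfig.tiny(input_size=32, feature_dim=16),
                           seed=0)
features = extract_features(extractor, images)
print(f"feature matrix: {features.F.shape[0]} images x "
      f"{features.F.shape[1]} features per image")
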