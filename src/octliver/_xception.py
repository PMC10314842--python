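"""Optional deep backbone: Xception with the binary head.

Requires the optional ``torch`` dependency (``pip install octliver[torch]``).
The trunk is the 36-layer depthwise-separable-convolution stack (entry,
middle and exit flows with residual connections in all modules but the
first and last); the head replaces the original classifier with global
average pooling, one fully connected output and a sigmoid, and the input is
a grayscale tile replicated onto the three channels.  Pretrained weights
are optional and must be supplied by the caller (no download happens here).
"""

from __future__ import annotations


def _require_torch():
    try:
        import torch
        from torch import nn
    except ImportError as exc:  # pragma: no cover - exercised only without torch
        raise ImportError(
            "the 'xception' backbone requires the optional torch dependency; "
            "install it or use backbone='small_cnn'"
        ) from exc
    return torch, nn


def build_xception(seed: int = 0, pretrained: bool = False):
    """Construct the modified Xception; returns a torch ``nn.Module``."""
    torch, nn = _require_torch()
    if pretrained:
        raise ValueError(
            "pretrained weights are not bundled; load a state dict onto the "
            "returned module instead"
        )
    torch.manual_seed(seed)

    class SeparableConv(nn.Module):
        def __init__(self, cin, cout, stride=1):
            super().__init__()
            self.depthwise = nn.Conv2d(cin, cin, 3, stride, 1, groups=cin, bias=False)
            self.pointwise = nn.Conv2d(cin, cout, 1, bias=False)
            self.bn = nn.BatchNorm2d(cout)

        def forward(self, x):
            return self.bn(self.pointwise(self.depthwise(x)))

    class Block(nn.Module):
        """Xception module: separable convs with a residual connection."""

        def __init__(self, cin, cout, reps, stride=1, start_relu=True):
            super().__init__()
            layers = []
            c = cin
            for r in range(reps):
                if start_relu or r > 0:
                    layers.append(nn.ReLU(inplace=True))
                layers.append(SeparableConv(c, cout))
                c = cout
            if stride != 1:
                layers.append(nn.MaxPool2d(3, stride, 1))
            self.stack = nn.Sequential(*layers)
            if cout != cin or stride != 1:
                self.skip = nn.Sequential(
                    nn.Conv2d(cin, cout, 1, stride, bias=False), nn.BatchNorm2d(cout)
                )
            else:
                self.skip = nn.Identity()

        def forward(self, x):
            return self.stack(x) + self.skip(x)

    class XceptionBinary(nn.Module):
        def __init__(self):
            super().__init__()
            self.stem = nn.Sequential(
                nn.Conv2d(3, 32, 3, 2, bias=False), nn.BatchNorm2d(32), nn.ReLU(True),
                nn.Conv2d(32, 64, 3, bias=False), nn.BatchNorm2d(64), nn.ReLU(True),
            )
            self.entry = nn.Sequential(
                Block(64, 128, 2, stride=2, start_relu=False),
                Block(128, 256, 2, stride=2),
                Block(256, 728, 2, stride=2),
            )
            self.middle = nn.Sequential(*[Block(728, 728, 3) for _ in range(8)])
            self.exit = nn.Sequential(
                Block(728, 1024, 2, stride=2),
                SeparableConv(1024, 1536), nn.ReLU(True),
                SeparableConv(1536, 2048), nn.ReLU(True),
            )
            self.fc = nn.Linear(2048, 1)

        def forward(self, x):
            h = self.exit(self.middle(self.entry(self.stem(x))))
            gap = h.mean(dim=(2, 3))
            return self.fc(gap).squeeze(1)

        def predict_proba(self, pixels, batch_size: int = 8):
            import numpy as np

            self.eval()
            out = []
            with torch.no_grad():
                for start in range(0, len(pixels), batch_size):
                    chunk = np.asarray(pixels[start : start + batch_size], dtype="float32") / 255.0
                    x = torch.from_numpy(chunk).unsqueeze(1).repeat(1, 3, 1, 1)
                    out.append(torch.sigmoid(self.forward(x)).numpy())
            return np.concatenate(out).astype(np.float64)

    return XceptionBinary()
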