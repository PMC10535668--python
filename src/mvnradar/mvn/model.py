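"""The MVN: masked-autoencoder pretraining network and the frozen-encoder
ViT regression head.

Windows are tokenized as non-overlapping time patches (``patch_len`` frames
x all range bins, flattened).  During pretraining a random 40% of the data
tokens are masked; the encoder sees only the visible tokens (plus a
learnable class token that is never masked), and the lighter decoder
reinserts learnable mask tokens at the masked positions and reconstructs
the full patch grid.  For heart-rate regression the pretrained encoder is
frozen, runs on the full unmasked sequence, and a small ViT reads the class
vector out through an MLP head into a single scalar, scaled to BPM.
"""
from __future__ import annotations

import numpy as np

from ..config import MVNConfig
from .autodiff import (Tensor, assemble_sequence, broadcast_to, concat,
                       slice_axis1, take_rows)
from .nn import Linear, Module, Parameter, TransformerStack

__all__ = ["patchify", "unpatchify", "random_mask", "MaskedAutoencoder",
           "MVNModel", "build_mvn"]


def patchify(matrix: np.ndarray, patch_len: int) -> np.ndarray:
    """(n_bins x W) window -> (W/patch_len, n_bins*patch_len) token matrix."""
    matrix = np.asarray(matrix)
    n_bins, width = matrix.shape
    if width % patch_len:
        raise ValueError(f"patch_len {patch_len} does not divide window length {width}")
    n_tok = width // patch_len
    # token i = matrix[:, i*pl:(i+1)*pl] flattened bin-major
    return matrix.reshape(n_bins, n_tok, patch_len).transpose(1, 0, 2).reshape(n_tok, n_bins * patch_len)


def unpatchify(tokens: np.ndarray, n_bins: int, patch_len: int) -> np.ndarray:
    """Inverse of :func:`patchify`; bit-exact round trip."""
    tokens = np.asarray(tokens)
    n_tok = tokens.shape[0]
    return tokens.reshape(n_tok, n_bins, patch_len).transpose(1, 0, 2).reshape(n_bins, n_tok * patch_len)


def random_mask(
    n_tokens: int, ratio: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform token mask: (sorted visible indices, sorted masked indices).

    Exactly ``round(ratio * n_tokens)`` data tokens are masked; the class
    token is not part of the index space and is therefore never masked.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n_masked = round(ratio * n_tokens)
    if n_masked == 0 or n_masked == n_tokens:
        raise ValueError(f"ratio {ratio} masks {n_masked} of {n_tokens} tokens")
    perm = rng.permutation(n_tokens)
    return np.sort(perm[n_masked:]), np.sort(perm[:n_masked])


class MAEEncoder(Module):
    def __init__(self, cfg: MVNConfig, n_tokens: int, rng: np.random.Generator):
        self.embed = Linear(cfg.patch_dim, cfg.enc_dim, rng, "enc.embed")
        self.cls_token = Parameter(rng.normal(0, 0.02, cfg.enc_dim), "enc.cls")
        self.pos = Parameter(rng.normal(0, 0.02, (n_tokens + 1, cfg.enc_dim)), "enc.pos")
        self.stack = TransformerStack(cfg.enc_layers, cfg.enc_dim, cfg.heads,
                                      cfg.ffn_dim, rng, "enc")
        self.n_tokens = n_tokens

    def __call__(self, tokens: np.ndarray, positions: np.ndarray) -> Tensor:
        """Encode visible tokens.

        tokens (B, K, patch_dim); positions (B, K) are ORIGINAL token
        indices used to look up positional embeddings.  Output includes the
        class token at sequence position 0: (B, K+1, enc_dim).
        """
        batch = tokens.shape[0]
        x = self.embed(Tensor(tokens)) + take_rows(self.pos, np.asarray(positions) + 1)
        cls = broadcast_to(
            (self.cls_token + take_rows(self.pos, np.array([0]))).reshape(1, 1, -1),
            (batch, 1, x.shape[-1]),
        )
        return self.stack(concat([cls, x], axis=1))


class MAEDecoder(Module):
    def __init__(self, cfg: MVNConfig, n_tokens: int, rng: np.random.Generator):
        self.proj = Linear(cfg.enc_dim, cfg.dec_dim, rng, "dec.proj")
        self.mask_token = Parameter(rng.normal(0, 0.02, cfg.dec_dim), "dec.mask")
        self.pos = Parameter(rng.normal(0, 0.02, (n_tokens + 1, cfg.dec_dim)), "dec.pos")
        self.stack = TransformerStack(cfg.dec_layers, cfg.dec_dim, cfg.heads,
                                      cfg.ffn_dim, rng, "dec")
        self.head = Linear(cfg.dec_dim, cfg.patch_dim, rng, "dec.head")
        self.n_tokens = n_tokens

    def __call__(self, latents: Tensor, visible_idx: np.ndarray) -> Tensor:
        """Reconstruct the full patch grid: (B, n_tokens, patch_dim)."""
        z = self.proj(latents)
        cls_lat = slice_axis1(z, 0, 1)
        data_lat = slice_axis1(z, 1, z.shape[1])
        full = assemble_sequence(data_lat, self.mask_token, visible_idx, self.n_tokens)
        full = full + take_rows(self.pos, np.arange(1, self.n_tokens + 1))
        cls_lat = cls_lat + take_rows(self.pos, np.array([0]))
        seq = self.stack(concat([cls_lat, full], axis=1))
        out = self.head(seq)
        return slice_axis1(out, 1, self.n_tokens + 1)


class MaskedAutoencoder(Module):
    """Asymmetric encoder/decoder trained to reconstruct masked tokens."""

    def __init__(self, cfg: MVNConfig, n_tokens: int, rng: np.random.Generator):
        self.cfg = cfg
        self.n_tokens = n_tokens
        self.encoder = MAEEncoder(cfg, n_tokens, rng)
        self.decoder = MAEDecoder(cfg, n_tokens, rng)

    def draw_masks(self, batch: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        vis, masked = zip(*(random_mask(self.n_tokens, self.cfg.mask_ratio, rng)
                            for _ in range(batch)))
        return np.stack(vis), np.stack(masked)

    def forward(self, tokens: np.ndarray, visible_idx: np.ndarray) -> Tensor:
        b_idx = np.arange(tokens.shape[0])[:, None]
        visible_tokens = tokens[b_idx, visible_idx]
        latents = self.encoder(visible_tokens, visible_idx)
        return self.decoder(latents, visible_idx)

    def loss(self, tokens: np.ndarray, visible_idx: np.ndarray,
             masked_idx: np.ndarray) -> Tensor:
        """Reconstruction MSE, on masked tokens only by default."""
        recon = self.forward(tokens, visible_idx)
        if self.cfg.loss_on_masked_only:
            b_idx = np.arange(tokens.shape[0])[:, None]
            from .autodiff import gather_tokens

            pred = gather_tokens(recon, masked_idx)
            target = tokens[b_idx, masked_idx]
        else:
            pred, target = recon, tokens
        err = pred - Tensor(target)
        return (err * err).mean()


class ViTHead(Module):
    """Projection + positional embedding + transformer stack + MLP head on
    the class vector."""

    def __init__(self, cfg: MVNConfig, n_tokens: int, rng: np.random.Generator):
        self.proj = Linear(cfg.enc_dim, cfg.vit_dim, rng, "vit.proj")
        self.pos = Parameter(rng.normal(0, 0.02, (n_tokens + 1, cfg.vit_dim)), "vit.pos")
        self.stack = TransformerStack(cfg.vit_layers, cfg.vit_dim, cfg.heads,
                                      cfg.ffn_dim, rng, "vit")
        self.mlp1 = Linear(cfg.vit_dim, cfg.vit_dim, rng, "vit.mlp1")
        self.mlp2 = Linear(cfg.vit_dim, 1, rng, "vit.mlp2")

    def __call__(self, latents: Tensor) -> Tensor:
        z = self.proj(latents) + take_rows(self.pos, np.arange(latents.shape[1]))
        z = self.stack(z)
        cls = slice_axis1(z, 0, 1).reshape(z.shape[0], -1)
        return self.mlp2(self.mlp1(cls).gelu()).reshape(z.shape[0])


class LinearHead(Module):
    """Ablation head: one linear layer on the class vector."""

    def __init__(self, cfg: MVNConfig, n_tokens: int, rng: np.random.Generator):
        self.fc = Linear(cfg.enc_dim, 1, rng, "lin.fc")

    def __call__(self, latents: Tensor) -> Tensor:
        cls = slice_axis1(latents, 0, 1).reshape(latents.shape[0], -1)
        return self.fc(cls).reshape(latents.shape[0])


class MVNModel(Module):
    """Frozen MAE encoder + regression head; outputs BPM."""

    def __init__(self, encoder: MAEEncoder, cfg: MVNConfig, n_tokens: int,
                 rng: np.random.Generator, head: str = "vit",
                 encoder_frozen: bool = True):
        self.cfg = cfg
        self.n_tokens = n_tokens
        self.encoder = encoder
        self.head_kind = head
        if head == "vit":
            self.head = ViTHead(cfg, n_tokens, rng)
        elif head == "linear":
            self.head = LinearHead(cfg, n_tokens, rng)
        else:
            raise ValueError(f"unknown head {head!r}")
        self.encoder_frozen = encoder_frozen
        self._apply_freeze()

    def _apply_freeze(self) -> None:
        for p in self.encoder.parameters():
            p.requires_grad = not self.encoder_frozen

    def trainable_parameters(self) -> list[Parameter]:
        params = self.head.parameters()
        if not self.encoder_frozen:
            params = self.encoder.parameters() + params
        return params

    def forward(self, tokens: np.ndarray) -> Tensor:
        """Scaled prediction (label BPM / label_scale); no masking."""
        batch, n_tok, _ = tokens.shape
        positions = np.broadcast_to(np.arange(n_tok), (batch, n_tok))
        latents = self.encoder(tokens, positions)
        return self.head(latents)

    def predict(self, tokens: np.ndarray) -> np.ndarray:
        """Heart-rate prediction in BPM for a (B, n_tokens, patch_dim) batch."""
        return self.forward(tokens).data * self.cfg.label_scale


def build_mvn(encoder: MAEEncoder, cfg: MVNConfig, n_tokens: int,
              seed: int | None = None, head: str = "vit",
              encoder_frozen: bool = True) -> MVNModel:
    """Attach a fresh regression head to a (pretrained) encoder."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return MVNModel(encoder, cfg, n_tokens, rng, head=head,
                    encoder_frozen=encoder_frozen)
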