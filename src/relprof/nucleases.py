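"""Nuclease cut-site models.

Two enzymes shape footprint ends:

* MNase trims unprotected mRNA back to the ribosome boundary.  Its 3'
  boundary sits ``delta_mnase`` nt downstream of the first nucleotide of the
  A-site codon (+12 by default, giving the familiar +15 start-codon and +12
  stop-codon metagene peaks), with optional Gaussian jitter, and it prefers
  to cut immediately 5' of A or T.
* RelE enters an empty A site and cleaves after the second nucleotide of the
  A-site codon (``delta_rele`` = 1, i.e. 3' end one nt past the codon's
  first nt, giving the +4 start peak).  Codons ending in C (NNC) are instead
  cut after their third nucleotide with probability ``p_nnc``.  A
  multiplicative preference for C at -1 and G at +1 of the cut is applied by
  acceptance-rejection thinning of cleavage events, so the realised 3'-end
  geometry is never perturbed.  Ribosomes whose A site is stably occupied
  (bound tRNA or release factor) block RelE with probability
  ``p_block_occupied`` and are digested with MNase geometry instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Nuclease(str, Enum):
    MNASE = "MNASE"
    RELE = "RELE"


@dataclass(frozen=True)
class MNaseModel:
    """Micrococcal-nuclease boundary model."""

    delta_mnase: int = 12
    p_cut_before_AT: float | None = 0.8
    boundary_jitter_sd: float = 0.0
    max_reposition: int = 3
    five_prime_offset: int = 20  # A-site first nt -> footprint 5' end, upstream

    def __post_init__(self) -> None:
        if self.p_cut_before_AT is not None and not 0 <= self.p_cut_before_AT <= 1:
            raise ValueError("p_cut_before_AT must lie in [0, 1]")
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary_jitter_sd must be >= 0")

    name = Nuclease.MNASE


@dataclass(frozen=True)
class RelEModel:
    """RelE A-site cleavage model."""

    delta_rele: int = 1
    p_nnc: float = 1.0
    w_minus1_C: float = 3.0
    w_plus1_G: float = 3.0
    p_block_occupied: float = 1.0
    p_miscleave: float = 0.0  # uniform mis-cleavage over the A-site codon

    def __post_init__(self) -> None:
        for name in ("p_nnc", "p_block_occupied", "p_miscleave"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.w_minus1_C <= 0 or self.w_plus1_G <= 0:
            raise ValueError("preference weights must be > 0")

    name = Nuclease.RELE
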