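"""Independent brute-force re-implementation of the caller for tiny genomes.

Scalar, literal translation of the classification table and the cohort
rules, deliberately sharing no code with the package: every position of
every genome is classified with plain ifs and the five background rules
are applied in order.  Used to cross-check the vectorised caller.
"""

ALLELES = ["A", "C", "G", "T", "-"]


def oracle_classify(counts7, ref_base, masked):
    """(classification, mutant_allele, frequency) for one position."""
    cov = counts7[0]
    if masked:
        return "masked", None, 0.0
    if cov < 20:
        return "low_coverage", None, 0.0
    best_allele, best_count = None, 0
    strong = 0
    for i, a in enumerate(ALLELES):
        if a == ref_base:
            continue
        c = counts7[1 + i]
        if c > best_count:  # strictly greater: first max wins ties
            best_allele, best_count = a, c
        if c > 0 and c / cov >= 0.1:
            strong += 1
    freq = best_count / cov if best_count else 0.0
    if strong >= 2:
        return "undefined", best_allele, freq
    if freq < 0.1:
        return "hom_ref", None, freq
    if freq < 0.3:
        return "seq_error", best_allele, freq
    if freq < 0.8:
        return "het", best_allele, freq
    if freq <= 0.9:
        return "undefined", best_allele, freq
    return "hom_mut", best_allele, freq


def oracle_accept(focal_cls, focal_allele, background):
    """Literal background rules on (classification, allele) pairs."""
    mutant = [(c, a) for c, a in background if c in ("het", "hom_mut")]
    if any(a == focal_allele for _, a in mutant):
        return False
    if sum(1 for c, _ in background if c == "undefined") > 1:
        return False
    if mutant:  # a different mutation at the position
        return False
    if sum(1 for c, _ in background if c == "low_coverage") > 3:
        return False
    if sum(1 for c, _ in background if c == "hom_ref") < 6:
        return False
    return True


def oracle_call(focal_counts, bg_counts_list, ref_seq, masked):
    """Accepted (pos, allele, zygosity) set for one chromosome.

    ``focal_counts``/``bg_counts_list`` are (L, 7) integer arrays; ``masked``
    is a boolean array.
    """
    accepted = set()
    L = len(ref_seq)
    for p in range(L):
        cls, allele, _ = oracle_classify(focal_counts[p], ref_seq[p], masked[p])
        if cls not in ("het", "hom_mut"):
            continue
        background = [
            oracle_classify(bg[p], ref_seq[p], masked[p])[:2]
            for bg in bg_counts_list
        ]
        if oracle_accept(cls, allele, background):
            accepted.add((p, allele, "hom" if cls == "hom_mut" else "het"))
    return accepted
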