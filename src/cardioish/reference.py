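"""Reference Cardioish sentences reported for the original ECG corpora.

These are the published symbol sentences produced by the original
lead-rank pipeline on its two source datasets — an 11-class myocardial
infarction (MI) beat corpus and a 4-class mental-disorder beat corpus —
together with the published per-symbol frequency rows.  They are included as
worked examples for the tokenizer, the symbol-distribution statistics, and
the entropy computation; they are inputs, never expected outputs of this
package's own classifiers.

Note: re-tokenizing each sentence reproduces its own frequency row exactly
(194 tokens for MI, 188 for the mental-disorder corpus).  The Shannon
entropies of the two frequency rows are 3.5752 and 3.5637 bits respectively
(maximum log2(12) ≈ 3.5850 for 12 symbols).
"""

from __future__ import annotations

MI_SENTENCE = (
    "AVLV1SV2SAVRAVRLd2Ld2AVLV3AV4AV6LV4AV5LLd1V3AV1SV2SV2SV5LV3AV4AV2SV4ALd1"
    "V6LV3ALd1V5LLd3AVFAVFLd1AVFV2SLd1Ld2V6LV6LAVLV4AAVRAVFLd2V4AV4AV4AV4AAVR"
    "V1SLd2Ld1V3AAVLV2SV3AV6LV2SV3AV6LAVRV1SLd3AVRAVRV5LV1SV5LV2SAVLLd3AVRV4A"
    "Ld1V2SAVLAVLLd2Ld2AVFV1SLd2V2SLd3AVRV2SAVLLd3V2SLd2V5LV5LAVRV3AV5LLd1AVF"
    "Ld2AVRAVRV1SAVFLd3V6LV1SLd3V6LV1SV4ALd1AVRV3AAVRLd1Ld1V6LAVLV3AAVLV3ALd2"
    "V3ALd1V3AV3AAVRV3AAVRV2SV5LLd2V4AV6LLd2V6LLd1AVLV4AAVLAVFLd2V4AV5LAVLLd2"
    "V5LAVFV1SV1SLd1Ld3V5LV5LV6LLd1V4ALd3AVFAVRLd3V4AV2SLd3Ld3Ld3AVLV3AV1SLd1"
    "V3AAVFAVLV6LV6LLd2V1SV2SLd2V1SLd2V3AAVFV5LAVLV5LV1SV5LV4AAVFV1SAVRV1SV3A"
    "V1SV6L"
)

MENTAL_SENTENCE = (
    "V4AV2SV5LV3AAVLV1SV2SV2SV6LV4AV4AV4AAVFAVRLd2V6LV3AV1SLd1V5LV5LV5LLd2AVL"
    "V2SV3AAVFLd3V1SLd3AVLV2SV6LV6LLd1AVLV3AV4AV2SV4ALd1Ld2Ld2V5LV3AV3ALd3V4A"
    "V4AAVLV4AAVRV1SLd2AVLAVLV2SAVLAVFLd1Ld3AVFAVRLd2AVRAVFV2SV5LAVLV4AAVRAVR"
    "V5LV1SV1SV1SAVLLd3Ld3V5LV2SAVRV5LAVLV6LLd1AVRAVLV4AV1SAVRV3AV5LLd3V2SLd3"
    "Ld3AVRAVRV2SLd3V6LAVFV2SLd1Ld1V4AV5LAVFAVFV3AAVLV5LV2SV3AAVRLd3Ld1AVFV4A"
    "Ld1Ld3V6LLd3V3ALd1AVLLd2Ld1V4AAVLLd1V1SV3AAVLV3ALd2AVRV1SV2SV6LLd2AVFV5L"
    "V5LLd1V6LV2SAVFV3AAVRV5LV1SAVLLd3V3AAVRV4AV2SV6LV1SLd1V2SAVFAVRV1SV1SV5L"
    "AVFV1SV5LV6LLd3Ld3V5LAVRLd2V2SLd2V3ALd3AVLLd1AVRV1SAVRLd1V1S"
)

#: Published per-symbol frequency rows, alphabet order
#: (Ld1, Ld2, Ld3, AVR, AVL, AVF, V1S, V2S, V3A, V4A, V5L, V6L).
MI_FREQUENCIES = (16, 18, 13, 18, 16, 13, 18, 15, 19, 17, 16, 15)
MENTAL_FREQUENCIES = (16, 11, 17, 19, 18, 13, 17, 18, 15, 15, 18, 11)
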