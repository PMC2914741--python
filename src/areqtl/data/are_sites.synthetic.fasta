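>site01 synthetic ARE training site (TGAC...GC core); stand-in collection, not the original curated set
ATGACTCAGCA
>site02 synthetic ARE training site
GTGACTCAGCA
>site03 synthetic ARE training site
ATGACTTGGCA
>site04 synthetic ARE training site
ATGACAAAGCC
>site05 synthetic ARE training site
GTGACCCGGCA
>site06 synthetic ARE training site
ATGACTCAGCT
>site07 synthetic ARE training site
ATGACGTAGCA
>site08 synthetic ARE training site
GTGACTAAGCA
>site09 synthetic ARE training site
ATGACCTGGCA
>site10 synthetic ARE training site
ATGACTCGGCG
>site11 synthetic ARE training site
GTGACATAGCA
>site12 synthetic ARE training site
ATGACTTAGCA
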