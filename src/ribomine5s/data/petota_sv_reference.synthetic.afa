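; synthetic reference alignment for spacer structural-variant typing
>master
GGGTTAAAGCTGAGAAAATCGGAACTTATACGGATCATGCGCGCCGAATAGCAGGGCACACCTGATTTGTGGAGCGAGGAAGAGACTGAGTATTACAGATGCGAGGAACCCGAACCTCCATTCTTAGCCTATGCAATTGCATGAGTAGTGTAGGCGCTCTCCCGGAGCAGACCCCTAAGACTGAGCCATTCCCGCTATTAATCGTCGGAAATGCA
>SVA_example
GGGTTAAAGCTGAGAAAATCGGAACTTATACGGATCATGCGCGCCGAATAGCAGGGCACACCTGATTTGTGGAGCGAGGAAGAGACTGAGTATTACAGATGCGAGGAACCCGAACCTCCATTCTTAGCCTATGCAATTGCATGAGTAGTGTAGGCGCTCTC--------GACCCCTAAGACTGAGCCATTCCCGCTATTAATCGTCGGAAATGCA
>SVB_example
GGGTTAAAGCTGAGAAAATCGGAACTTATACGGATCATGCGCGCCGAATAGCAGGGCACACCTGATTTGTGGAGCGAGGAAGAGACTGAGTATTACAGATGCGAGGAACCCGAACCTCCATT---------TGCAATTGCATGAGTAGTGTAGGCGCTCTC--------GACCCCTAAGACTGAGCCATTCCCGCTATTAATCGTCGGAAATGCA
>SVC_example
GGGTTAAAGCTGAGAAAATCGGAACTTATACGGATCATGCGCGCCGAATAGCAGGGCACA------------AGCGAGGAAGAGACTGAGTATTACAGATGCGAGGAACCCGAACCTCCATTCTTAGCCTATGCAATTGCATGAGTAGTGTAGGCGCTCTC--------GACCCCTAAGACTGAGCCATTCCCGCTATTAATCGTCGGAAATGCA
>SVD_example
GGGTTAAAGCTGAGAAAATCGGAACTTATACGGATCATGCGCGCCGAATAGCAGGGCACA------------AGCGAGGAAGAGACTGAGTATTACAGATGCGAGGAACCCGAACCTCCATTCTTAGCCTATGCAATTGCATGAGTAGTGTAGGCGCTCTCCCGGAGCAGACCCCTAAGACTGAGCCATTCCCGCTATTAATCGTCGGAAATGCA
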