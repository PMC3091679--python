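name	pattern	description
ABRE	MACGYGB	abscisic acid responsiveness
AGL2	NNWNCCA[W]4TRG[W]2AN	binding sequence of AGL2 (SEPALLATA1)
ARFAT	TGTCTC	auxin response factor binding site
ASF1	TGACG	activation of genes by auxin/salicylic acid
CARGAT	CC[W]6GG	CArG box of MADS-box flowering-time genes
CPBCSPOR	TATTAG	cytokinin-enhanced protein binding in vitro
ERELEE4	AWTTCAAA	ethylene responsive element
GARE	TAACAGA	gibberellin-responsive element
GAHV	TAACAAA	gibberellin response complex
WUSTAG	TTAATGG	target sequence of WUS
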