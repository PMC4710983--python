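term	name	condition	gene
GO:0005975	carbohydrate metabolic process	AA	YLR258W
GO:0005975	carbohydrate metabolic process	AA	YML070W
GO:0005975	carbohydrate metabolic process	AA	YPR160W
GO:0005975	carbohydrate metabolic process	FF	YDL095W
GO:0005975	carbohydrate metabolic process	FF	YDR001C
GO:0005975	carbohydrate metabolic process	FF	YEL040W
GO:0005975	carbohydrate metabolic process	FF	YFL053W
GO:0005975	carbohydrate metabolic process	FF	YGR256W
GO:0005975	carbohydrate metabolic process	FF	YKL085W
GO:0005975	carbohydrate metabolic process	FF	YML100W
GO:0005975	carbohydrate metabolic process	FF	YMR105C
GO:0005975	carbohydrate metabolic process	FF	YPR160W
GO:0005975	carbohydrate metabolic process	AAFF	YBR001C
GO:0005975	carbohydrate metabolic process	AAFF	YKL085W
GO:0006520	cellular amino acid metabolic process	AA	YLR142W
GO:0006520	cellular amino acid metabolic process	FF	YDR007W
GO:0006520	cellular amino acid metabolic process	FF	YDR380W
GO:0006520	cellular amino acid metabolic process	FF	YGL184C
GO:0006520	cellular amino acid metabolic process	FF	YJR010W
GO:0006520	cellular amino acid metabolic process	FF	YJR137C
GO:0006520	cellular amino acid metabolic process	FF	YKL001C
GO:0006520	cellular amino acid metabolic process	FF	YLR142W
GO:0006520	cellular amino acid metabolic process	FF	YMR169C
GO:0006520	cellular amino acid metabolic process	AAFF	YDL168W
GO:0006520	cellular amino acid metabolic process	AAFF	YDR007W
GO:0006520	cellular amino acid metabolic process	AAFF	YDR035W
GO:0006520	cellular amino acid metabolic process	AAFF	YFL030W
GO:0006520	cellular amino acid metabolic process	AAFF	YGL184C
GO:0006520	cellular amino acid metabolic process	AAFF	YJL101C
GO:0006520	cellular amino acid metabolic process	AAFF	YJR010W
GO:0006520	cellular amino acid metabolic process	AAFF	YJR137C
GO:0006520	cellular amino acid metabolic process	AAFF	YMR169C
GO:0006629	lipid metabolic process	AA	YOL151W
GO:0006629	lipid metabolic process	AA	YPL095C
GO:0006629	lipid metabolic process	FF	YGL055W
GO:0006629	lipid metabolic process	FF	YGL205W
GO:0006629	lipid metabolic process	FF	YKL150W
GO:0006629	lipid metabolic process	FF	YNL169C
GO:0006629	lipid metabolic process	AAFF	YGL205W
GO:0006629	lipid metabolic process	AAFF	YKL150W
GO:0006629	lipid metabolic process	AAFF	YOL151W
GO:0006629	lipid metabolic process	AAFF	YPL095C
GO:0006811	ion transport	AA	YCL025C
GO:0006811	ion transport	AA	YML116W
GO:0006811	ion transport	FF	YBR054W
GO:0006811	ion transport	FF	YGR142W
GO:0006811	ion transport	FF	YJR095W
GO:0006811	ion transport	FF	YOR306C
GO:0006811	ion transport	FF	YPL274W
GO:0006811	ion transport	AAFF	YGR055W
GO:0006811	ion transport	AAFF	YGR142W
GO:0006811	ion transport	AAFF	YJR095W
GO:0006811	ion transport	AAFF	YML116W
GO:0006811	ion transport	AAFF	YOL130W
GO:0006811	ion transport	AAFF	YOR306C
GO:0055086	nucleobase-containing small molecule metabolic process	AA	YDL234C
GO:0055086	nucleobase-containing small molecule metabolic process	AA	YDR011W
GO:0055086	nucleobase-containing small molecule metabolic process	AA	YKL173W
GO:0055086	nucleobase-containing small molecule metabolic process	AA	YOR153W
GO:0055086	nucleobase-containing small molecule metabolic process	FF	YFL037W
GO:0055086	nucleobase-containing small molecule metabolic process	FF	YGR256W
GO:0055086	nucleobase-containing small molecule metabolic process	FF	YKL151C
GO:0055086	nucleobase-containing small molecule metabolic process	FF	YMR105C
GO:0055086	nucleobase-containing small molecule metabolic process	FF	YMR120C
GO:0055086	nucleobase-containing small molecule metabolic process	FF	YNL200C
GO:0055086	nucleobase-containing small molecule metabolic process	AAFF	YDR011W
GO:0055086	nucleobase-containing small molecule metabolic process	AAFF	YGR281W
GO:0055086	nucleobase-containing small molecule metabolic process	AAFF	YOR153W
GO:0042221	response to chemical	AA	YBR008C
GO:0042221	response to chemical	AA	YDR011W
GO:0042221	response to chemical	AA	YDR346C
GO:0042221	response to chemical	AA	YGR234W
GO:0042221	response to chemical	AA	YML070W
GO:0042221	response to chemical	AA	YML116W
GO:0042221	response to chemical	AA	YOR153W
GO:0042221	response to chemical	FF	YDL095W
GO:0042221	response to chemical	FF	YFL014W
GO:0042221	response to chemical	FF	YFL037W
GO:0042221	response to chemical	FF	YFL053W
GO:0042221	response to chemical	FF	YGR088W
GO:0042221	response to chemical	FF	YKL150W
GO:0042221	response to chemical	FF	YOL052C-A
GO:0042221	response to chemical	AAFF	YBR008C
GO:0042221	response to chemical	AAFF	YDR011W
GO:0042221	response to chemical	AAFF	YDR533C
GO:0042221	response to chemical	AAFF	YGR088W
GO:0042221	response to chemical	AAFF	YJL101C
GO:0042221	response to chemical	AAFF	YKL150W
GO:0042221	response to chemical	AAFF	YML116W
GO:0042221	response to chemical	AAFF	YOR153W
GO:0006979	response to oxidative stress	AA	YDR346C
GO:0006979	response to oxidative stress	AA	YGR234W
GO:0006979	response to oxidative stress	FF	YFL014W
GO:0006979	response to oxidative stress	FF	YGR088W
GO:0006979	response to oxidative stress	FF	YKL150W
GO:0006979	response to oxidative stress	FF	YOL052C-A
GO:0006979	response to oxidative stress	AAFF	YDR533C
GO:0006979	response to oxidative stress	AAFF	YGR088W
GO:0006979	response to oxidative stress	AAFF	YJL101C
GO:0006979	response to oxidative stress	AAFF	YKL150W
GO:0055085	transmembrane transport	AA	YBR008C
GO:0055085	transmembrane transport	AA	YCL025C
GO:0055085	transmembrane transport	AA	YDR011W
GO:0055085	transmembrane transport	AA	YML116W
GO:0055085	transmembrane transport	AA	YOR153W
GO:0055085	transmembrane transport	FF	YBR054W
GO:0055085	transmembrane transport	FF	YCR023C
GO:0055085	transmembrane transport	FF	YHR092C
GO:0055085	transmembrane transport	FF	YHR096C
GO:0055085	transmembrane transport	FF	YJR095W
GO:0055085	transmembrane transport	FF	YOR306C
GO:0055085	transmembrane transport	FF	YPL274W
GO:0055085	transmembrane transport	AAFF	YBR008C
GO:0055085	transmembrane transport	AAFF	YDR011W
GO:0055085	transmembrane transport	AAFF	YGR055W
GO:0055085	transmembrane transport	AAFF	YGR281W
GO:0055085	transmembrane transport	AAFF	YJR095W
GO:0055085	transmembrane transport	AAFF	YML116W
GO:0055085	transmembrane transport	AAFF	YOL130W
GO:0055085	transmembrane transport	AAFF	YOR153W
GO:0055085	transmembrane transport	AAFF	YOR306C
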