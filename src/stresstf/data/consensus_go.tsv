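term	name	gene
GO:0005975	carbohydrate metabolic process	YBR001C
GO:0005975	carbohydrate metabolic process	YBR105C
GO:0005975	carbohydrate metabolic process	YCL018W
GO:0005975	carbohydrate metabolic process	YCL040W
GO:0005975	carbohydrate metabolic process	YCR005C
GO:0005975	carbohydrate metabolic process	YDL174C
GO:0005975	carbohydrate metabolic process	YDL193W
GO:0005975	carbohydrate metabolic process	YER062C
GO:0005975	carbohydrate metabolic process	YFL053W
GO:0005975	carbohydrate metabolic process	YGL134W
GO:0005975	carbohydrate metabolic process	YGR254W
GO:0005975	carbohydrate metabolic process	YHR046C
GO:0005975	carbohydrate metabolic process	YHR174W
GO:0005975	carbohydrate metabolic process	YJR096W
GO:0005975	carbohydrate metabolic process	YKL201C
GO:0005975	carbohydrate metabolic process	YLL026W
GO:0005975	carbohydrate metabolic process	YML100W
GO:0005975	carbohydrate metabolic process	YMR135C
GO:0005975	carbohydrate metabolic process	YMR145C
GO:0005975	carbohydrate metabolic process	YNR001C
GO:0005975	carbohydrate metabolic process	YOL032W
GO:0005975	carbohydrate metabolic process	YOL059W
GO:0005975	carbohydrate metabolic process	YOL086C
GO:0005975	carbohydrate metabolic process	YOL136C
GO:0005975	carbohydrate metabolic process	YOR299W
GO:0042221	response to chemical	YBR006W
GO:0042221	response to chemical	YBR101C
GO:0042221	response to chemical	YCR021C
GO:0042221	response to chemical	YDL124W
GO:0042221	response to chemical	YDR135C
GO:0042221	response to chemical	YFL053W
GO:0042221	response to chemical	YFR022W
GO:0042221	response to chemical	YGR008C
GO:0042221	response to chemical	YJL034W
GO:0042221	response to chemical	YJL128C
GO:0042221	response to chemical	YJR096W
GO:0042221	response to chemical	YKL062W
GO:0042221	response to chemical	YKL073W
GO:0042221	response to chemical	YKL109W
GO:0042221	response to chemical	YKR066C
GO:0042221	response to chemical	YKR071C
GO:0042221	response to chemical	YLL026W
GO:0042221	response to chemical	YLR350W
GO:0042221	response to chemical	YMR250W
GO:0042221	response to chemical	YNL007C
GO:0042221	response to chemical	YOL081W
GO:0042221	response to chemical	YPL026C
GO:0042221	response to chemical	YPL239W
GO:0042221	response to chemical	YPR036W-A
GO:0055085	transmembrane transport	YAL005C
GO:0055085	transmembrane transport	YBR287W
GO:0055085	transmembrane transport	YCL025C
GO:0055085	transmembrane transport	YCR021C
GO:0055085	transmembrane transport	YCR023C
GO:0055085	transmembrane transport	YDR046C
GO:0055085	transmembrane transport	YDR086C
GO:0055085	transmembrane transport	YDR135C
GO:0055085	transmembrane transport	YDR345C
GO:0055085	transmembrane transport	YEL024W
GO:0055085	transmembrane transport	YER103W
GO:0055085	transmembrane transport	YGL006W
GO:0055085	transmembrane transport	YGR065C
GO:0055085	transmembrane transport	YGR138C
GO:0055085	transmembrane transport	YHL036W
GO:0055085	transmembrane transport	YHR092C
GO:0055085	transmembrane transport	YJL034W
GO:0055085	transmembrane transport	YKL073W
GO:0055085	transmembrane transport	YKL174C
GO:0055085	transmembrane transport	YLL024C
GO:0055085	transmembrane transport	YNL125C
GO:0055085	transmembrane transport	YPL036W
GO:0055085	transmembrane transport	YPR156C
GO:0006520	cellular amino acid metabolic process	YBR006W
GO:0006520	cellular amino acid metabolic process	YCL018W
GO:0006520	cellular amino acid metabolic process	YCR005C
GO:0006520	cellular amino acid metabolic process	YDL182W
GO:0006520	cellular amino acid metabolic process	YDR135C
GO:0006520	cellular amino acid metabolic process	YGL196W
GO:0006520	cellular amino acid metabolic process	YIR034C
GO:0006520	cellular amino acid metabolic process	YJR078W
GO:0006520	cellular amino acid metabolic process	YJR103W
GO:0006520	cellular amino acid metabolic process	YJR109C
GO:0006520	cellular amino acid metabolic process	YJR137C
GO:0006520	cellular amino acid metabolic process	YLR142W
GO:0006520	cellular amino acid metabolic process	YMR250W
GO:0006520	cellular amino acid metabolic process	YNL037C
GO:0006520	cellular amino acid metabolic process	YNL073W
GO:0006520	cellular amino acid metabolic process	YNR001C
GO:0006520	cellular amino acid metabolic process	YOL086C
GO:0006520	cellular amino acid metabolic process	YOR136W
GO:0006520	cellular amino acid metabolic process	YOR202W
GO:0006520	cellular amino acid metabolic process	YPL160W
GO:0006520	cellular amino acid metabolic process	YPR035W
GO:0055086	nucleobase-containing small molecule metabolic process	YCR021C
GO:0055086	nucleobase-containing small molecule metabolic process	YDR135C
GO:0055086	nucleobase-containing small molecule metabolic process	YDR529C
GO:0055086	nucleobase-containing small molecule metabolic process	YEL021W
GO:0055086	nucleobase-containing small molecule metabolic process	YEL024W
GO:0055086	nucleobase-containing small molecule metabolic process	YEL041W
GO:0055086	nucleobase-containing small molecule metabolic process	YER036C
GO:0055086	nucleobase-containing small molecule metabolic process	YER037W
GO:0055086	nucleobase-containing small molecule metabolic process	YJR078W
GO:0055086	nucleobase-containing small molecule metabolic process	YJR103W
GO:0055086	nucleobase-containing small molecule metabolic process	YKL073W
GO:0055086	nucleobase-containing small molecule metabolic process	YMR145C
GO:0055086	nucleobase-containing small molecule metabolic process	YNL088W
GO:0055086	nucleobase-containing small molecule metabolic process	YNL220W
GO:0055086	nucleobase-containing small molecule metabolic process	YOL059W
GO:0055086	nucleobase-containing small molecule metabolic process	YOL081W
GO:0055086	nucleobase-containing small molecule metabolic process	YOL086C
GO:0055086	nucleobase-containing small molecule metabolic process	YOR204W
GO:0055086	nucleobase-containing small molecule metabolic process	YPL036W
GO:0055086	nucleobase-containing small molecule metabolic process	YPR181C
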