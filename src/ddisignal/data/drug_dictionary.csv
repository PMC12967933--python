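synonym,ingredient,class
RIVAROXABAN,rivaroxaban,DOAC
XARELTO,rivaroxaban,DOAC
APIXABAN,apixaban,DOAC
ELIQUIS,apixaban,DOAC
EDOXABAN,edoxaban,DOAC
EDOXABAN TOSYLATE,edoxaban,DOAC
SAVAYSA,edoxaban,DOAC
LIXIANA,edoxaban,DOAC
DABIGATRAN,dabigatran,DOAC
DABIGATRAN ETEXILATE,dabigatran,DOAC
DABIGATRAN ETEXILATE MESYLATE,dabigatran,DOAC
PRADAXA,dabigatran,DOAC
FLUOXETINE,fluoxetine,SSRI
FLUOXETINE HYDROCHLORIDE,fluoxetine,SSRI
PROZAC,fluoxetine,SSRI
SARAFEM,fluoxetine,SSRI
PAROXETINE,paroxetine,SSRI
PAROXETINE HYDROCHLORIDE,paroxetine,SSRI
PAXIL,paroxetine,SSRI
SEROXAT,paroxetine,SSRI
FLUVOXAMINE,fluvoxamine,SSRI
FLUVOXAMINE MALEATE,fluvoxamine,SSRI
LUVOX,fluvoxamine,SSRI
SERTRALINE,sertraline,SSRI
SERTRALINE HYDROCHLORIDE,sertraline,SSRI
ZOLOFT,sertraline,SSRI
CITALOPRAM,citalopram,SSRI
CITALOPRAM HYDROBROMIDE,citalopram,SSRI
CELEXA,citalopram,SSRI
CIPRAMIL,citalopram,SSRI
ESCITALOPRAM,escitalopram,SSRI
ESCITALOPRAM OXALATE,escitalopram,SSRI
LEXAPRO,escitalopram,SSRI
CIPRALEX,escitalopram,SSRI
VENLAFAXINE,venlafaxine,SNRI
VENLAFAXINE HYDROCHLORIDE,venlafaxine,SNRI
EFFEXOR,venlafaxine,SNRI
EFFEXOR XR,venlafaxine,SNRI
DESVENLAFAXINE,desvenlafaxine,SNRI
DESVENLAFAXINE SUCCINATE,desvenlafaxine,SNRI
PRISTIQ,desvenlafaxine,SNRI
DULOXETINE,duloxetine,SNRI
DULOXETINE HYDROCHLORIDE,duloxetine,SNRI
CYMBALTA,duloxetine,SNRI
BUPROPION,bupropion,OTHER_AD
BUPROPION HYDROCHLORIDE,bupropion,OTHER_AD
WELLBUTRIN,bupropion,OTHER_AD
ZYBAN,bupropion,OTHER_AD
MIRTAZAPINE,mirtazapine,OTHER_AD
REMERON,mirtazapine,OTHER_AD
AGOMELATINE,agomelatine,OTHER_AD
VALDOXAN,agomelatine,OTHER_AD
TRAZODONE,trazodone,OTHER_AD
TRAZODONE HYDROCHLORIDE,trazodone,OTHER_AD
DESYREL,trazodone,OTHER_AD
OLEPTRO,trazodone,OTHER_AD
VORTIOXETINE,vortioxetine,OTHER_AD
VORTIOXETINE HYDROBROMIDE,vortioxetine,OTHER_AD
TRINTELLIX,vortioxetine,OTHER_AD
BRINTELLIX,vortioxetine,OTHER_AD
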