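>Q9NZC2 TREM2_HUMAN Triggering receptor expressed on myeloid cells 2 precursor
MEPLRLLILLFVTELSGAHNTTVFQGVAGQSLQVSCPYDSMKHWGRRKAWCRQLGEKGPC
QRVVSTHNLWLLSFLRRWNGSTAITDDTLGGTLTITLRNLQPHDAGLYQCQSLHGSEADT
LRKVLVEVLADPLDHRDAGDLWFPGESESFEDAHVEHSISRSLLEGEIPFPPTSILLLLA
CIFLIKILAASALWAAAWHGQKPGTHPPSELDCGHDPGYQLQTLPGLRDT
>Q6ZMJ4 IL34_HUMAN Interleukin-34 precursor
MPRGFTWLRYLGILLGVALGNEPLEMWPLTQNEECTVTGFLRDKLQYRSRLQYMKHYFPI
NYKISVPYEGVFRIANVTRLQRAQVSEREMRYLWVLVSLSATESVQDVLLEGHPSWKYLQ
EVETLLLNVQQGLTDVEVSPKVESVLSLLNAPGPNLKLVRPKALLDNCFRVMELLYCSCC
KQSSVLNWQDCEVPSPQSCSPEPSLQYAATQLYPPPPWSPSSPPHSTGSVRPVRAQGEGL
LP
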