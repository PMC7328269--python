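#!/usr/bin/env Rscript
# Independent reference for the moderated t-test: limma lmFit + eBayes on a
# probes x samples CSV with a two-group design; writes t, p, and the
# moderation hyperparameters.
suppressMessages(library(limma))
args <- commandArgs(trailingOnly = TRUE)
dat <- as.matrix(read.csv(args[[1]], header = FALSE))
grp <- scan(args[[2]], what = integer(), quiet = TRUE)
design <- model.matrix(~grp)
fit <- eBayes(lmFit(dat, design))
out <- data.frame(
  effect = fit$coefficients[, 2],
  t = fit$t[, 2],
  p = fit$p.value[, 2],
  s2_post = fit$s2.post
)
write.table(out, args[[3]], sep = ",", row.names = FALSE, col.names = TRUE)
cat(fit$df.prior, fit$s2.prior, sep = "\n", file = args[[4]])
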